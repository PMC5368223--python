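"""PCA and OPLS-DA with the full resampling validation suite.

OPLS-DA is implemented from scratch as the single-response orthogonal
projection recursion: the predictive weight is ``w = X'y/||X'y||``; each
orthogonal component removes from X the part of its loading direction that
is orthogonal to ``w`` (so the orthogonal scores are exactly uncorrelated
with the class encoding), and with zero orthogonal components the model
collapses to one-component PLS.

Model validity is judged the way discriminant metabolomics models are:
repeated stratified two-fold cross-validation gives Q2Y (1 - PRESS/TSS) and
per-sample cross-validated predictions; AUROC (Mann-Whitney pair statistic)
and the misclassification rate are computed on those CV predictions; and a
label-permutation test (default B = 2000) yields an empirical p-value per
statistic, p = (1 + #{permuted >= observed})/(B + 1) for larger-is-better
statistics and mirrored for misclassification.

:class:`OPLSDA` is a scikit-learn compatible classifier (fit / predict /
decision_function / transform); the module-level helpers operate on plain
arrays for speed inside the permutation loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.decomposition import PCA as _SkPCA
from sklearn.model_selection import StratifiedKFold


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PcaModel:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components (orthonormal columns)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def fit_pca(X, n_components: int) -> PcaModel:
    """SVD-based PCA on internally centered data."""
    X = np.asarray(X, dtype=float)
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in 1..{max_comp}")
    pca = _SkPCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return PcaModel(
        scores=scores,
        loadings=pca.components_.T,
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean=pca.mean_,
    )


# ---------------------------------------------------------------------------
# O-PLS core (plain arrays; Xc and yc centered)

def _opls_fit_core(Xc: np.ndarray, yc: np.ndarray, n_orth: int) -> dict:
    """Single-response O-PLS recursion on centered X, y."""
    Xd = Xc.copy()
    xty = Xd.T @ yc
    norm = np.linalg.norm(xty)
    if norm == 0:
        raise ValueError("X carries no covariance with y; cannot fit")
    w = xty / norm
    w_o, p_o, t_o = [], [], []
    for _ in range(n_orth):
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        wo = p - (w @ p) * w  # remove the predictive direction
        nwo = np.linalg.norm(wo)
        if nwo < 1e-12:
            raise ValueError("orthogonal component collapsed; reduce n_orth")
        wo /= nwo
        to = Xd @ wo
        po = Xd.T @ to / (to @ to)
        Xd = Xd - np.outer(to, po)
        w_o.append(wo)
        p_o.append(po)
        t_o.append(to)
    t = Xd @ w
    tt = t @ t
    p = Xd.T @ t / tt
    b = (yc @ t) / tt
    yhat = b * t
    ssy = float(yc @ yc)
    r2y = 1.0 - float((yc - yhat) @ (yc - yhat)) / ssy if ssy > 0 else np.nan
    ssx = float((Xc * Xc).sum())
    recon = np.outer(t, p)
    for to, po in zip(t_o, p_o):
        recon += np.outer(to, po)
    r2x = float((recon * recon).sum()) / ssx if ssx > 0 else np.nan
    return {
        "w": w, "p": p, "t": t, "b": b,
        "w_orth": np.array(w_o).reshape(n_orth, -1) if n_orth else np.zeros((0, Xc.shape[1])),
        "p_orth": np.array(p_o).reshape(n_orth, -1) if n_orth else np.zeros((0, Xc.shape[1])),
        "t_orth": np.array(t_o).reshape(n_orth, -1).T if n_orth else np.zeros((Xc.shape[0], 0)),
        "r2y": r2y, "r2x": r2x,
    }


def _opls_predict_core(core: dict, Xc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict centered responses for centered new data."""
    Xd = Xc.copy()
    for wo, po in zip(core["w_orth"], core["p_orth"]):
        to = Xd @ wo
        Xd = Xd - np.outer(to, po)
    t = Xd @ core["w"]
    return core["b"] * t, t


def _encode(y) -> tuple[np.ndarray, list, dict]:
    y = np.asarray(y)
    classes = sorted(pd.unique(y).tolist())
    if len(classes) != 2:
        raise ValueError(f"exactly 2 classes required, got {classes}")
    mapping = {classes[0]: -1.0, classes[1]: 1.0}
    enc = np.array([mapping[v] for v in y])
    for c in classes:
        if (y == c).sum() < 3:
            raise ValueError(f"class {c!r} has fewer than 3 samples")
    return enc, classes, mapping


class OPLSDA(BaseEstimator, ClassifierMixin, TransformerMixin):
    """Two-class OPLS-DA with one predictive and ``n_orth`` orthogonal components.

    X is mean-centered internally (scaling such as Pareto is applied
    upstream); the class labels are encoded -1/+1 (sorted order) and
    centered.  Fitted attributes follow sklearn conventions:

    ``weights_`` (w), ``loadings_`` (p), ``scores_`` (t), ``coef_`` (b),
    ``orth_weights_``, ``orth_loadings_``, ``orth_scores_``, ``r2x_``,
    ``r2y_``, ``classes_``, ``class_map_``, ``x_mean_``, ``y_mean_``.
    """

    def __init__(self, n_orth: int = 1):
        self.n_orth = n_orth

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if self.n_orth < 0:
            raise ValueError("n_orth must be >= 0")
        if self.n_orth >= min(X.shape) :
            raise ValueError("n_orth must be below the rank of X")
        enc, classes, mapping = _encode(y)
        self.classes_ = np.array(classes)
        self.class_map_ = mapping
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = enc.mean()
        self._y_enc = enc
        core = _opls_fit_core(X - self.x_mean_, enc - self.y_mean_, self.n_orth)
        self._core = core
        self.weights_ = core["w"]
        self.loadings_ = core["p"]
        self.scores_ = core["t"]
        self.coef_ = core["b"]
        self.orth_weights_ = core["w_orth"]
        self.orth_loadings_ = core["p_orth"]
        self.orth_scores_ = core["t_orth"]
        self.r2y_ = core["r2y"]
        self.r2x_ = core["r2x"]
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        yhat, _ = _opls_predict_core(self._core, X - self.x_mean_)
        return yhat + self.y_mean_

    def transform(self, X):
        """Predictive score t for new samples."""
        X = np.asarray(X, dtype=float)
        _, t = _opls_predict_core(self._core, X - self.x_mean_)
        return t[:, None]

    def predict(self, X):
        # threshold at the midpoint of the -1/+1 encoding
        return np.where(self.decision_function(X) >= 0.0,
                        self.classes_[1], self.classes_[0])


def fit_oplsda(X, y, n_orth: int = 1) -> OPLSDA:
    """Functional wrapper over :class:`OPLSDA`."""
    return OPLSDA(n_orth=n_orth).fit(X, y)


# ---------------------------------------------------------------------------
# Validation statistics

def auroc(scores, labels) -> float:
    """Area under the ROC curve as the Mann-Whitney pair statistic.

    Equals (#{pos > neg} + 0.5 #{ties}) / (n_pos * n_neg), with the
    positive class the larger label in sorted order.
    """
    scores = np.asarray(scores, dtype=float)
    enc, classes, _ = _encode_labels_lenient(labels)
    pos = scores[enc == 1]
    neg = scores[enc == -1]
    ranks = rankdata(scores)
    n_pos, n_neg = len(pos), len(neg)
    u = ranks[enc == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _encode_labels_lenient(labels):
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    enc = np.where(labels == classes[1], 1, -1)
    return enc, classes, {classes[0]: -1, classes[1]: 1}


def misclassification(predicted, labels, threshold: float = 0.0) -> float:
    """Fraction of samples whose thresholded prediction mismatches the label.

    ``predicted`` holds continuous class-value predictions on the -1/+1
    encoding scale; *threshold* defaults to the encoding midpoint (0).
    """
    predicted = np.asarray(predicted, dtype=float)
    enc, _, _ = _encode_labels_lenient(labels)
    if len(predicted) != len(enc):
        raise ValueError("need a prediction for every sample")
    calls = np.where(predicted >= threshold, 1, -1)
    return float(np.mean(calls != enc))


def cross_validate_q2(
    X, y, folds: int = 2, repeats: int = 20, n_orth: int = 1, seed: int = 0,
):
    """Repeated stratified k-fold Q2Y with retained CV predictions.

    Q2Y = 1 - PRESS/TSS per repeat, averaged over repeats; PRESS sums the
    squared held-out errors of the encoded class value, TSS is the total sum
    of squares of the centered encoding.  Returns
    ``(q2_mean, per_repeat, cv_predictions)`` with predictions averaged over
    repeats (on the -1/+1 scale).
    """
    X = np.asarray(X, dtype=float)
    enc, classes, _ = _encode(y)
    counts = pd.Series(list(y)).value_counts()
    if (counts < folds).any():
        raise ValueError(f"every class needs at least {folds} members")
    tss = float(((enc - enc.mean()) ** 2).sum())
    rng = np.random.default_rng(seed)
    per_repeat = []
    pred_sum = np.zeros(len(enc))
    strat = np.asarray(y)
    for _ in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True,
            random_state=int(rng.integers(2 ** 31 - 1)),
        )
        press = 0.0
        for train, test in skf.split(X, strat):
            Xtr, ytr = X[train], enc[train]
            xm, ym = Xtr.mean(axis=0), ytr.mean()
            core = _opls_fit_core(Xtr - xm, ytr - ym, n_orth)
            yhat, _ = _opls_predict_core(core, X[test] - xm)
            yhat = yhat + ym
            press += float(((enc[test] - yhat) ** 2).sum())
            pred_sum[test] += yhat
        per_repeat.append(1.0 - press / tss)
    return float(np.mean(per_repeat)), per_repeat, pred_sum / repeats


@dataclass
class PermutationReport:
    """Observed validation statistics and their label-permutation nulls."""

    observed: dict  # statistic -> value
    distributions: dict  # statistic -> np.ndarray of length B
    p_values: dict  # statistic -> empirical p
    B: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed": {k: float(v) for k, v in self.observed.items()},
            "p_values": {k: float(v) for k, v in self.p_values.items()},
            "B": self.B,
            "seed": self.seed,
            "distributions": {k: list(map(float, v)) for k, v in self.distributions.items()},
        }


#: statistics where larger values mean a better model
_LARGER_BETTER = ("q2", "r2y", "auroc")


def _model_statistics(X, enc_labels, n_orth, folds, repeats, seed):
    xm = X.mean(axis=0)
    enc, _, _ = _encode(enc_labels)
    core = _opls_fit_core(X - xm, enc - enc.mean(), n_orth)
    q2, _, cvpred = cross_validate_q2(
        X, enc_labels, folds=folds, repeats=repeats, n_orth=n_orth, seed=seed
    )
    return {
        "q2": q2,
        "r2y": core["r2y"],
        "auroc": auroc(cvpred, enc_labels),
        "misclassification": misclassification(cvpred, enc_labels),
    }


def permutation_test(
    X, y, n_orth: int = 1, B: int = 2000, folds: int = 2,
    cv_repeats: int = 5, seed: int = 0, observed_cv_repeats: int | None = None,
) -> PermutationReport:
    """Label-permutation null for Q2, R2Y, AUROC and misclassification.

    Each permutation shuffles the labels (class sizes preserved), refits the
    model and its cross-validation, and recomputes all four statistics.
    Empirical p = (1 + #{permuted at least as good})/(B + 1), where "good"
    means larger for Q2/R2Y/AUROC and smaller for misclassification.
    ``observed_cv_repeats`` lets the observed model use more CV repeats than
    the permutations (defaults to ``cv_repeats``).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    obs = _model_statistics(
        X, y, n_orth, folds, observed_cv_repeats or cv_repeats,
        seed=int(rng.integers(2 ** 31 - 1)),
    )
    dists = {k: np.empty(B) for k in obs}
    for b in range(B):
        perm = rng.permutation(len(y))
        stats = _model_statistics(
            X, y[perm], n_orth, folds, cv_repeats,
            seed=int(rng.integers(2 ** 31 - 1)),
        )
        for k, v in stats.items():
            dists[k][b] = v
    pvals = {}
    for k in obs:
        if k in _LARGER_BETTER:
            better = int((dists[k] >= obs[k]).sum())
        else:
            better = int((dists[k] <= obs[k]).sum())
        pvals[k] = (1 + better) / (B + 1)
    return PermutationReport(
        observed=obs, distributions=dists, p_values=pvals, B=B, seed=seed
    )


@dataclass
class VariableStatistics:
    """Per-feature covariance/correlation with the predictive score.

    The (cov, corr) pairs draw the covariance-based pseudo-spectrum and the
    S-plot; ``class_corr`` color-codes features by their correlation with
    the class encoding.
    """

    cov: pd.Series
    corr: pd.Series
    class_corr: pd.Series
    zero_variance: pd.Series  # bool flag per feature


def variable_statistics(X, model: OPLSDA, feature_names=None) -> VariableStatistics:
    """cov(t, x) and corr(t, x) per feature for a fitted model."""
    X = np.asarray(X, dtype=float)
    t = model.scores_
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    tc = t - t.mean()
    cov = Xc.T @ tc / (n - 1)
    sx = Xc.std(axis=0, ddof=1)
    st = tc.std(ddof=1)
    zero = sx == 0
    denom = np.where(zero, 1.0, sx * st)
    corr = np.where(zero, 0.0, cov / denom)
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"x{i}" for i in range(X.shape[1])]
    )
    ye = model._y_enc - model._y_enc.mean()
    covy = Xc.T @ ye / (n - 1)
    sy = ye.std(ddof=1)
    class_corr = np.where(zero, 0.0, covy / np.where(zero, 1.0, sx * sy))
    return VariableStatistics(
        cov=pd.Series(cov, index=names),
        corr=pd.Series(corr, index=names),
        class_corr=pd.Series(class_corr, index=names),
        zero_variance=pd.Series(zero, index=names),
    )
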