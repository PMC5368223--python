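import numpy as np
import pytest

from hljdopt.chemometrics import (
    OPLSDA,
    auroc,
    cross_validate_q2,
    fit_oplsda,
    fit_pca,
    misclassification,
    permutation_test,
    variable_statistics,
)


class TestPCA:
    def test_rank_one_explains_everything(self, rng):
        u = rng.normal(size=20)
        v = rng.normal(size=8)
        X = np.outer(u, v)
        model = fit_pca(X, 2)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_projection_identity(self, rng):
        X = rng.normal(size=(15, 6))
        model = fit_pca(X, 4)
        np.testing.assert_allclose(
            model.scores, (X - model.mean) @ model.loadings, atol=1e-10
        )

    def test_loadings_orthonormal(self, rng):
        X = rng.normal(size=(20, 10))
        model = fit_pca(X, 5)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)

    def test_explained_variance_matches_eigen_oracle(self, rng):
        X = rng.normal(size=(30, 6))
        model = fit_pca(X, 6)
        evals = np.linalg.eigvalsh(np.cov(X, rowvar=False))[::-1]
        np.testing.assert_allclose(
            model.explained_variance_ratio, evals / evals.sum(), atol=1e-8
        )

    def test_component_limit(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.normal(size=(5, 3)), 5)


def _nipals_pls1(X, y_enc):
    """One-component NIPALS PLS oracle (single response)."""
    Xc = X - X.mean(axis=0)
    yc = y_enc - y_enc.mean()
    w = Xc.T @ yc
    w = w / np.linalg.norm(w)
    return Xc @ w


class TestOPLSDA:
    def test_zero_orth_reduces_to_pls1(self, two_cloud):
        X, y = two_cloud
        model = OPLSDA(n_orth=0).fit(X, y)
        t_pls = _nipals_pls1(X, model._y_enc)
        np.testing.assert_allclose(model.scores_, t_pls, atol=1e-10)

    @pytest.mark.parametrize("n_orth", [1, 2, 3])
    def test_orthogonal_scores_uncorrelated_with_class(self, two_cloud, n_orth):
        X, y = two_cloud
        model = OPLSDA(n_orth=n_orth).fit(X, y)
        yc = model._y_enc - model._y_enc.mean()
        for j in range(n_orth):
            t_o = model.orth_scores_[:, j]
            assert abs(t_o @ yc) < 1e-8 * np.linalg.norm(t_o) * np.linalg.norm(yc)
            # also orthogonal to the predictive score
            assert abs(t_o @ model.scores_) < 1e-6 * np.linalg.norm(t_o) * np.linalg.norm(model.scores_)

    def test_predictive_scores_centered(self, two_cloud):
        X, y = two_cloud
        model = OPLSDA(n_orth=1).fit(X, y)
        assert abs(model.scores_.mean()) < 1e-10

    def test_separated_clouds_r2y(self, two_cloud):
        X, y = two_cloud
        model = fit_oplsda(X, y, n_orth=1)
        assert 0.9 < model.r2y_ <= 1.0
        assert (model.predict(X) == y).all()

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="2 classes"):
            OPLSDA().fit(X, ["a"] * 10)

    def test_tiny_class_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="fewer than 3"):
            OPLSDA().fit(X, ["a"] * 8 + ["b"] * 2)

    def test_excessive_orth_rejected(self, rng):
        X = rng.normal(size=(8, 4))
        y = ["a"] * 4 + ["b"] * 4
        with pytest.raises(ValueError, match="n_orth"):
            OPLSDA(n_orth=4).fit(X, y)

    def test_sklearn_params_roundtrip(self):
        model = OPLSDA(n_orth=2)
        assert model.get_params() == {"n_orth": 2}
        model.set_params(n_orth=0)
        assert model.n_orth == 0


class TestCrossValidation:
    def test_perfect_predictor_gives_q2_one(self):
        y = np.array(["a"] * 6 + ["b"] * 6)
        enc = np.where(y == "b", 1.0, -1.0)
        X = enc[:, None]  # the single feature IS the class value
        q2, per_repeat, pred = cross_validate_q2(X, y, repeats=3, n_orth=0, seed=0)
        assert q2 == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(pred, enc, atol=1e-10)

    def test_uninformative_features_give_q2_near_zero_or_less(self, rng):
        X = rng.normal(size=(30, 10))
        y = np.array(["a"] * 15 + ["b"] * 15)
        q2, _, _ = cross_validate_q2(X, y, repeats=5, seed=1)
        assert q2 < 0.3

    def test_manual_two_fold_press_oracle(self):
        # fixed split, repeats=1: recompute PRESS by hand with the same folds
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 5))
        y = np.array(["a"] * 6 + ["b"] * 6)
        X[y == "b"] += 1.0
        seed = 4
        q2, _, _ = cross_validate_q2(X, y, folds=2, repeats=1, n_orth=0, seed=seed)

        from sklearn.model_selection import StratifiedKFold

        enc = np.where(y == "b", 1.0, -1.0)
        inner = np.random.default_rng(seed)
        skf = StratifiedKFold(
            n_splits=2, shuffle=True, random_state=int(inner.integers(2 ** 31 - 1))
        )
        press = 0.0
        for train, test in skf.split(X, y):
            Xc = X[train] - X[train].mean(axis=0)
            yc = enc[train] - enc[train].mean()
            w = Xc.T @ yc
            w /= np.linalg.norm(w)
            t = Xc @ w
            b = (yc @ t) / (t @ t)
            t_new = (X[test] - X[train].mean(axis=0)) @ w
            yhat = b * t_new + enc[train].mean()
            press += ((enc[test] - yhat) ** 2).sum()
        tss = ((enc - enc.mean()) ** 2).sum()
        assert q2 == pytest.approx(1 - press / tss, abs=1e-10)

    def test_class_smaller_than_folds_rejected(self, rng):
        X = rng.normal(size=(8, 3))
        y = ["a"] * 5 + ["b"] * 3
        with pytest.raises(ValueError, match="at least"):
            cross_validate_q2(X, y, folds=4)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 2, 3, 7, 8, 9], ["n"] * 3 + ["p"] * 3) == 1.0

    def test_all_ties(self):
        assert auroc([5.0] * 6, ["n"] * 3 + ["p"] * 3) == 0.5

    def test_brute_force_pair_oracle(self):
        scores = np.array([3.0, 2.0, 1.0, 2.5, 0.5, 0.0])
        labels = ["p", "p", "p", "n", "n", "n"]
        # brute force over all 9 (pos, neg) pairs
        pos, neg = scores[:3], scores[3:]
        wins = sum(
            1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
        )
        assert auroc(scores, labels) == pytest.approx(wins / 9)
        assert auroc(scores, labels) == pytest.approx(7.0 / 9)

    def test_matches_sklearn_on_random_data(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=40)
        labels = np.array(["a", "b"])[rng.integers(0, 2, size=40)]
        assert auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels == "b", scores)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 2], ["a", "a"])


class TestMisclassification:
    @pytest.mark.parametrize(
        "pred,expected",
        [
            ([-1, -1, 1, 1], 0.0),
            ([1, 1, -1, -1], 1.0),
            ([-1, -1, 1, -1], 0.25),
        ],
    )
    def test_counting(self, pred, expected):
        labels = ["a", "a", "b", "b"]
        assert misclassification(pred, labels) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="every sample"):
            misclassification([1.0], ["a", "b"])


class TestPermutationTest:
    @pytest.fixture(scope="class")
    def separated_report(self, two_cloud_cls):
        X, y = two_cloud_cls
        return permutation_test(X, y, B=99, cv_repeats=1, seed=5)

    @pytest.fixture(scope="class")
    def two_cloud_cls(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 20))
        X[:20, 0] += 5.0
        return X, np.array(["a"] * 20 + ["b"] * 20)

    def test_strong_separation_gives_minimal_p(self, separated_report):
        assert separated_report.p_values["q2"] == pytest.approx(1 / 100)
        assert separated_report.p_values["auroc"] == pytest.approx(1 / 100)

    def test_empirical_p_formula(self, separated_report):
        rep = separated_report
        for stat in ("q2", "r2y", "auroc"):
            better = (rep.distributions[stat] >= rep.observed[stat]).sum()
            assert rep.p_values[stat] == pytest.approx((1 + better) / (rep.B + 1))
        better = (
            rep.distributions["misclassification"]
            <= rep.observed["misclassification"]
        ).sum()
        assert rep.p_values["misclassification"] == pytest.approx(
            (1 + better) / (rep.B + 1)
        )

    def test_distribution_lengths_and_p_range(self, separated_report):
        for stat, dist in separated_report.distributions.items():
            assert len(dist) == separated_report.B
            assert 0 < separated_report.p_values[stat] <= 1

    def test_observed_worse_than_all_permutations_gives_p_one(self, rng):
        # constant-ish X cannot beat label permutations; force the boundary
        # by checking the formula on a tiny handmade report
        rep = permutation_test(
            rng.normal(size=(12, 3)), ["a"] * 6 + ["b"] * 6, B=10,
            cv_repeats=1, seed=0,
        )
        for stat in ("q2", "auroc"):
            worst = (rep.distributions[stat] >= rep.observed[stat]).all()
            if worst:
                assert rep.p_values[stat] == 1.0

    def test_separable_power_across_seeds(self):
        # planted 3-sigma shift, n=20/class: permutation p <= 0.01 nearly always
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(40, 10))
            X[:20, 0] += 3.0
            y = np.array(["a"] * 20 + ["b"] * 20)
            rep = permutation_test(X, y, B=199, cv_repeats=1, seed=seed)
            if rep.p_values["q2"] <= 0.01:
                hits += 1
        assert hits >= int(0.95 * n_seeds)


class TestVariableStatistics:
    def test_feature_equal_to_score_has_corr_one(self, two_cloud):
        X, y = two_cloud
        model = OPLSDA(n_orth=0).fit(X, y)
        X2 = np.column_stack([X, model.scores_])
        model2 = OPLSDA(n_orth=0).fit(X2, y)
        stats = variable_statistics(X2, model2)
        # the appended feature is (close to) the score direction itself
        assert stats.corr.iloc[-1] > 0.99

    def test_definitional_oracle(self, two_cloud):
        X, y = two_cloud
        model = OPLSDA(n_orth=1).fit(X, y)
        stats = variable_statistics(X, model)
        t = model.scores_
        for j in [0, 3, 19]:
            x = X[:, j]
            cov = np.cov(x, t, ddof=1)[0, 1]
            corr = np.corrcoef(x, t)[0, 1]
            assert stats.cov.iloc[j] == pytest.approx(cov, rel=1e-8)
            assert stats.corr.iloc[j] == pytest.approx(corr, rel=1e-8)

    def test_sign_consistency_and_range(self, two_cloud):
        X, y = two_cloud
        model = OPLSDA(n_orth=1).fit(X, y)
        stats = variable_statistics(X, model)
        assert (stats.corr.abs() <= 1 + 1e-12).all()
        nz = (stats.cov != 0) & (stats.corr != 0)
        assert (np.sign(stats.cov[nz]) == np.sign(stats.corr[nz])).all()

    def test_zero_variance_feature_flagged(self, two_cloud):
        X, y = two_cloud
        X2 = np.column_stack([X, np.full(len(X), 3.0)])
        model = OPLSDA(n_orth=0).fit(X2, y)
        stats = variable_statistics(X2, model)
        assert stats.zero_variance.iloc[-1]
        assert stats.corr.iloc[-1] == 0.0


class TestOptimism:
    def test_r2y_dominates_q2_across_seeds(self):
        # fitted fit is always at least as optimistic as cross-validation
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(24, 8))
            X[:12, 0] += rng.uniform(0, 2)
            y = np.array(["a"] * 12 + ["b"] * 12)
            model = OPLSDA(n_orth=1).fit(X, y)
            q2, _, _ = cross_validate_q2(X, y, repeats=3, seed=seed)
            if model.r2y_ >= q2:
                wins += 1
        assert wins == 50
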