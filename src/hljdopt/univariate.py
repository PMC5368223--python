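"""Fold-change and significance screening with BH-FDR control.

The screening contract: for each contrast (a group versus the MCAO model
group), per-metabolite fold change = ratio of arithmetic group means,
Student's two-tailed t-test (equal variance) for two groups or one-way
ANOVA with Tukey HSD pairwise contrasts for three or more, and
Benjamini-Hochberg adjustment across metabolites within the contrast.
A metabolite is called differential when its adjusted p falls below alpha,
with direction up (FC > 1) or down (FC < 1).

Also provides the z-scored group-mean table with significance stars that
feeds heatmap-style reporting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import BucketMatrix
from scipy.integrate import cumulative_trapezoid


def metabolite_integrals(source, regions: dict) -> pd.DataFrame:
    """Sum named metabolites' signal over their ppm integration regions.

    Parameters
    ----------
    source : BucketMatrix or list of Spectrum
    regions : {metabolite: [(ppm_lo, ppm_hi), ...]}; regions must be
        pairwise non-overlapping across metabolites.

    From a BucketMatrix, a region collects every bucket whose center lies
    inside it; from raw spectra, regions are trapezoid-integrated directly.
    """
    flat = []
    for name, ivals in regions.items():
        for lo, hi in ivals:
            if hi <= lo:
                raise ValueError(f"{name}: empty region ({lo}, {hi})")
            flat.append((name, float(lo), float(hi)))
    for i, (na, la, ha) in enumerate(flat):
        for nb, lb, hb in flat[i + 1:]:
            if na != nb and la < hb and lb < ha:
                raise ValueError(
                    f"overlapping integration regions: {na} ({la}-{ha}) "
                    f"and {nb} ({lb}-{hb})"
                )

    if isinstance(source, BucketMatrix):
        centers = source.centers
        out = {}
        for name, ivals in regions.items():
            mask = np.zeros(len(centers), dtype=bool)
            for lo, hi in ivals:
                mask |= (centers >= lo) & (centers < hi)
            out[name] = source.data.iloc[:, mask].sum(axis=1)
        return pd.DataFrame(out)

    rows, ids = [], []
    for s in source:
        asc_ppm, asc_int = s.ascending()
        cum = np.concatenate([[0.0], cumulative_trapezoid(asc_int, asc_ppm)])
        vals = {}
        for name, ivals in regions.items():
            total = 0.0
            for lo, hi in ivals:
                a, b = np.interp([lo, hi], asc_ppm, cum)
                total += b - a
            vals[name] = total
        rows.append(vals)
        ids.append(s.sample_id)
    return pd.DataFrame(rows, index=ids)


def group_test(values: pd.DataFrame, groups: pd.Series):
    """Per-metabolite raw p-values across groups.

    Two groups: Student's two-tailed equal-variance t-test (Series of p).
    Three or more: one-way ANOVA per metabolite plus Tukey HSD p for each
    pairwise contrast; returns ``(anova_p Series, tukey DataFrame)`` with
    tukey columns (metabolite, group1, group2, p).
    """
    groups = pd.Series(groups, index=values.index) if not isinstance(groups, pd.Series) else groups
    labels = list(dict.fromkeys(groups))
    for g in labels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")

    if len(labels) == 2:
        a = values[groups == labels[0]]
        b = values[groups == labels[1]]
        res = stats.ttest_ind(a, b, equal_var=True)
        p = pd.Series(np.asarray(res.pvalue), index=values.columns)
        return p.fillna(1.0)  # zero-variance identical groups -> t = 0 -> p = 1

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    anova_p, tukey_rows = {}, []
    arrs = {g: values[groups == g] for g in labels}
    for m in values.columns:
        samples = [arrs[g][m].to_numpy() for g in labels]
        if np.ptp(np.concatenate(samples)) == 0:
            anova_p[m] = 1.0  # all observations identical: F = 0
        else:
            f = stats.f_oneway(*samples)
            anova_p[m] = 1.0 if np.isnan(f.pvalue) else float(f.pvalue)
        tk = pairwise_tukeyhsd(values[m].to_numpy(), groups.to_numpy())
        for row in tk.summary().data[1:]:
            tukey_rows.append(
                {"metabolite": m, "group1": row[0], "group2": row[1],
                 "p": float(row[3])}
            )
    return pd.Series(anova_p), pd.DataFrame(tukey_rows)


def bh_adjust(p) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    adj = multipletests(arr, method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(adj, index=p.index)
    return adj


def fold_change(
    values: pd.DataFrame, groups: pd.Series, numerator: str, denominator: str
) -> pd.DataFrame:
    """FC = mean(numerator group) / mean(denominator group) per metabolite.

    Metabolites with a zero denominator mean get FC = NaN and a flag.
    """
    groups = pd.Series(groups, index=values.index) if not isinstance(groups, pd.Series) else groups
    for g in (numerator, denominator):
        if g not in set(groups):
            raise ValueError(f"group {g!r} not present")
    num = values[groups == numerator].mean()
    den = values[groups == denominator].mean()
    zero = den == 0
    fc = num / den.where(~zero)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(fc)
    return pd.DataFrame(
        {"fc": fc, "log2_fc": log2fc, "zero_denominator": zero}
    )


def differential_analysis(
    values: pd.DataFrame,
    groups: pd.Series,
    numerator: str,
    denominator: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full per-metabolite screen for one two-group contrast.

    Columns: fc, log2_fc, p (Student's t), q (BH across metabolites),
    direction in {up, down, unchanged} (called at q < alpha), test.
    """
    groups = pd.Series(groups, index=values.index) if not isinstance(groups, pd.Series) else groups
    sel = groups.isin([numerator, denominator])
    vals, grp = values[sel], groups[sel]
    p = group_test(vals, grp)
    q = bh_adjust(p)
    fc = fold_change(vals, grp, numerator, denominator)
    direction = pd.Series("unchanged", index=values.columns)
    direction[(fc["fc"] > 1) & (q < alpha)] = "up"
    direction[(fc["fc"] < 1) & (q < alpha)] = "down"
    out = fc.drop(columns="zero_denominator")
    out["p"] = p
    out["q"] = q
    out["direction"] = direction
    out["test"] = "student_t"
    out.index.name = "metabolite"
    return out


def _stars(q: float) -> str:
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return ""


def heatmap_table(
    values: pd.DataFrame,
    groups: pd.Series,
    reference: str,
    alpha: float = 0.05,
):
    """Z-scored group means per metabolite plus significance stars.

    Each metabolite's group-mean vector is z-scored across groups (mean 0,
    SD 1, sample SD); stars mark each non-reference group's BH-adjusted
    t-test p against the reference: * < 0.05, ** < 0.01, *** < 0.001.
    Returns ``(z DataFrame, stars DataFrame)`` indexed by metabolite.
    """
    groups = pd.Series(groups, index=values.index) if not isinstance(groups, pd.Series) else groups
    labels = list(dict.fromkeys(groups))
    if reference not in labels:
        raise ValueError(f"reference group {reference!r} not present")
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    means = values.groupby(groups, sort=False).mean().reindex(labels)
    sd = means.std(axis=0, ddof=1)
    z = (means - means.mean(axis=0)) / sd.replace(0, np.nan)
    z = z.fillna(0.0).T  # metabolites x groups

    stars = pd.DataFrame("", index=values.columns, columns=labels)
    for g in labels:
        if g == reference:
            continue
        res = differential_analysis(values, groups, g, reference, alpha=alpha)
        stars[g] = res["q"].map(_stars)
    return z, stars
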