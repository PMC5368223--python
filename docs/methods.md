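# Methods

This note records the models, numerical choices and open-design decisions
behind `hljdopt`, and what the synthetic cohorts do and do not emulate.

## Study structure

Eleven groups: sham controls (NC), MCAO model (M) and nine herb-ratio
formulae (F1–F9). All inferential contrasts are two-group comparisons of a
group against M. The canonical Taguchi L9(3^4) array (4 factors, 3 levels,
9 runs) is generated with its defining invariants asserted: every level
appears three times per column, and every column pair covers all nine level
combinations exactly once. The printed F1–F9 dose matrix ships verbatim as
a separate fixture because it is *not* a balanced L9 (e.g. the Rc column
holds dose 3 five times, and the Rs column spans four distinct doses
1/2/4/8); orthogonality is therefore never asserted on it, and no mapping
from printed doses onto a 3-level scheme is invented. The "L9(4^3)" vs
"L9(3^4)" notational ambiguity in the source material is resolved as four
factors at three levels. No Taguchi marginal-means analysis is provided:
the study selects the winning formula by direct group comparison.

Infarct percentage I% = (Vc − Vi)/Vc × 100 may be negative when edema makes
the intact ipsilateral volume exceed the contralateral one; negative values
are returned with a warning rather than clamped, since silent clamping
would hide data problems.

## Synthetic cohorts

Concentrations are log-normal: for sample j in group g,
c_jm = baseline_m · 2^fc(g,m) · exp(ε_jm), ε ~ MVN(0, σ² R). Log-normality
keeps concentrations positive and makes effects multiplicative, so the
ratio of group means equals 2^fc exactly — the natural match for a
fold-change pipeline. Defaults (the simulated study conditions):

- |fc| = 1 (two-fold) in the model group for the 18 amino acids with
  published directions (14 up: Glu, Asp, Ile, Leu, GABA, Gly, Thr, Ala,
  Lys, Phe, Met, Trp, Ser, Orn; 4 down: 2-ABA, Arg, Tau, Pro), zero for
  the other five panel members.
- log-scale noise SD σ = 0.3 (≈30% CV), a typical within-group biological
  variability for tissue metabolomics.
- correlation structure R: three blocks seeded around Thr, Ala and Val
  (the three amino-acid clusters the study observes), within-block
  correlation 0.7, zero between; membership is configurable.
- treatment groups recover a fraction ρ of the model insult
  (fc_g = (1−ρ_g)·fc_M): ρ = 0.9 for F9 (the near-complete responder),
  0.7 for F1 and F5, 0.2–0.3 for the rest, mirroring the reported ranking
  of the formulae. NC carries no insult.

Spectra are sums of unit-area Lorentzians (multiplets as weighted peak
lists) over a 0.2–10 ppm axis, scaled by the sample's true concentrations,
plus an optional linear baseline, an optional broad 4.9-ppm water artifact,
optional per-sample global ppm shift (to exercise alignment), and additive
Gaussian noise. A small brain-extract-like library (lactate, NAA, creatine,
glycerol and ten amino acids at literature-typical shifts) drives the
default study. The generator does **not** emulate FIDs, phasing or baseline
distortion of raw data, chemical-shift drift beyond the global shift,
peak-shape changes with pH, or MS acquisition — targeted amino acids are
simulated at the concentration-table level. Passing tests therefore
demonstrate correctness of the *analysis chain* under a known generative
model, not robustness to every artifact of real spectra.

Determinism: every file the generator writes is formatted with fixed
precision and all randomness flows from one seed, so identical config +
seed gives byte-identical outputs. Pipeline stages derive sub-seeds as
SHA-256 of (master seed, stage name), so adding a stage never perturbs the
randomness of earlier ones.

## NMR preprocessing

- **Alignment**: the reference procedure is unspecified in the source
  material, so a standard deterministic choice is used — segment-wise
  (default 0.06 ppm) integer-lag cross-correlation against the median
  spectrum, lags bounded by ±0.02 ppm, vacated points filled with the
  segment edge value (icoshift-style). Normalized correlation with ties
  broken toward zero lag makes self-alignment exactly the identity.
- **Bucketing**: bucket value = trapezoid integral over [left, right),
  computed from one cumulative integral, which makes the sum of retained
  buckets equal the whole-region integral to machine precision and is
  invariant to grid density (unlike point sums). Partial edge buckets and
  buckets straddling the 4.65–5.25 ppm water band are dropped entirely —
  not truncated — so all retained buckets share one width; the edge list is
  reported for audit.
- **PQN**: classic four-step recipe (integral-normalize each sample to unit
  total; reference = element-wise median across all samples; per-sample
  quotients over reference-positive buckets; divide by the median
  quotient). The reference uses all samples, not controls only — the
  common, seedless default. PQN is idempotent and preserves within-sample
  ratios. Noise-floor integrals slightly below zero (an artifact of
  integrating pure noise) are clipped to zero when below 0.1% of the
  sample's total absolute signal; anything more negative is an error.
- **Scaling**: Pareto = center then divide by √SD (sample SD, n−1).
  Constant columns are centered, flagged and never divided.

## OPLS-DA and validation

Class encoding y ∈ {−1, +1} (sorted label order), centered; X is
mean-centered internally, any scaling happens upstream. Single-response
recursion: w ∝ X'y normalized; per orthogonal component, p = X't/(t't),
w_orth ∝ p − (w'p)w, t_orth = X w_orth, deflate X by t_orth p_orth'. Because
w_orth ⊥ w and X'y ∝ w, the orthogonal scores satisfy t_orth'y = 0 exactly.
With n_orth = 0 the model is one-component PLS. Default n_orth = 1,
overridable; no automatic component selection is attempted. An orthogonal
component whose weight collapses (rank exhausted) raises rather than
silently returning zeros.

Cross-validation is stratified k-fold (default 2 folds, 20 repeats), with
centering re-estimated inside each training fold. Q²Y = 1 − PRESS/TSS per
repeat, averaged; TSS is the total sum of squares of the centered encoding.
Cross-validated predictions (averaged over repeats) feed AUROC and the
misclassification rate, because both serve here as validation diagnostics,
not resubstitution summaries. AUROC is the Mann–Whitney pair statistic
(ties count 1/2), computed by ranking. Misclassification thresholds
predictions at the encoding midpoint (0).

The permutation test shuffles labels (class sizes preserved), refits and
re-cross-validates per permutation, and reports an empirical p per
statistic with the positively biased estimator p = (1 + #{better})/(B + 1);
"better" means larger Q²/R²Y/AUROC, smaller misclassification. B defaults
to 2000. The permutations may use fewer CV repeats than the observed model
(`cv_repeats` vs `observed_cv_repeats`) to keep B = 2000 tractable; for
calibration studies both must be equal, otherwise the observed statistic is
not exchangeable with the permuted ones.

## Univariate screening

Fold change = ratio of arithmetic group means (medians are not used);
FC(A,B)·FC(B,A) = 1. Two groups: Student's equal-variance two-tailed t-test
(identical groups give t = 0, p = 1). Three or more: one-way ANOVA plus
Tukey HSD per pairwise contrast. BH step-up adjustment runs across
metabolites within each contrast (via statsmodels, verified against the
direct step-up formula); differential calls require BH q < α (default 0.05)
— adjusted rather than raw p, a declared choice. Heatmap rows z-score the
group-mean vector (sample SD across groups); stars mark BH-adjusted p vs
the reference group at 0.05/0.01/0.001.

## Correlation networks

Edges require |r| > 0.3 and raw two-sided p < 0.05 (t-transform,
t = r√(n−2)/√(1−r²), df = n−2). Edge p-values are deliberately not
multiplicity-adjusted, mirroring standard practice for these displays.
Correlations are computed on the **pooled** samples of the two contrasted
groups: the sample set behind published differential networks is ambiguous,
and pooling preserves the disease-axis co-variation that makes hub
metabolites (e.g. threonine) emerge; a per-group alternative is a
one-line change (pass a subset of samples). Structure-similarity edges come
from a curated amino-acid family pair list (editable CSV; threshold 0.6 on
the similarity value) — no chemistry engine is embedded, and any numeric
similarity map can be supplied instead. Nodes are restricted to the
contrast's differential metabolites; hub ranking counts correlation edges
only, with ties broken by summed |r| then name. Note that with raw-p edge
screening, spurious edges between truly uncorrelated metabolites appear at
the ~5% pair rate, so connected components of a thresholded network merge
distinct correlation blocks in a substantial fraction of cohorts at n = 40;
exact block recovery by components should not be expected at these
thresholds and sample sizes.

## Targeted-assay QC

Calibration is unweighted OLS of the analyte/IS peak-area ratio on the
standard concentration (1/x or 1/x² weighting is available but off by
default, since unweighted is the declared baseline); r² is the coefficient
of determination, identical for simple OLS to squared Pearson r of fitted
vs observed. LLOQ is the lowest level with S/N strictly greater than 10 —
a level at exactly 10 does not qualify. Precision/accuracy use RSD% =
100·SD/mean (n−1 SD) and RE% = 100·(mean − nominal)/nominal with the
≤15%/±15% windows; matrix effect passes inside [85, 115]; stability per
storage condition reuses the same arithmetic, conditions being labels, not
modeled processes. All pass/fail flags are pure functions of the reported
percentages.

## Problem sizes

The packaged test-suite and acceptance-script runs use reduced sizes chosen
to keep a desk run fast while leaving every statistical check well-powered:
studies of 5–10 samples/group on 0.002–0.005-ppm grids, B = 20–200
permutations, 50–500 Monte-Carlo repetitions depending on the check. The
pipeline defaults remain the full printed settings (0.015-ppm buckets,
0.2–10 ppm, water band excluded, 2-fold CV, B = 2000, |r| > 0.3, p < 0.05).

## Known limitations

- Two-class OPLS-DA only; no multi-class extension.
- No phasing/baseline correction of raw FIDs; inputs are already-processed
  two-column spectra.
- No metabolite identification: bucket-to-metabolite integration regions
  and assignment tables are user-supplied.
- Tukey HSD p-values come from statsmodels' studentized-range
  implementation; degenerate all-identical inputs short-circuit to p = 1.
- The synthetic generator's effect sizes and variances are stated defaults,
  not estimates fitted to any real cohort.
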