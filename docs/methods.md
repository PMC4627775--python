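# Methods

This note records the statistical models implemented in `nmrasca`, the
defaults chosen where the methodology is genuinely open, and what the
synthetic-data tests do and do not establish about real data.

## Data model

A cohort is a samples × buckets intensity matrix `X` with a two-factor
design: every sample (one animal, sacrificed once) belongs to exactly one
(time, dose) cell. Buckets are fixed-width (default 0.01 ppm) integrals of
the 1D ¹H spectrum; solvent and contaminant windows are excluded; each row
is normalized to its total spectral area, so features are relative
intensities that sum to 1 (a closure constraint that all downstream
statements inherit).

**Bucket boundary convention.** Bucket *i* covers
`[start + i·w, start + (i+1)·w)`. An exclusion window removes the buckets
strictly interior to it plus the bucket touching its upper edge; the single
bucket whose left edge coincides with the window's lower edge is retained.
A window of width `W` therefore removes `W/w − 1` buckets. Under this
convention the serum grid (δ 0.70–9.00, exclusions 4.40–5.10, 3.60–3.70,
1.10–1.25) retains 830 − 69 − 9 − 14 = 738 buckets and the liver grid
(0.80–10.00, exclusion 4.50–5.00) retains 920 − 49 = 871. Other conventions
could produce the same counts; this one is the package default and the one
the tests pin down. ppm comparisons use a 1e-6 ppm absolute tolerance; axes
are presented in descending NMR order but stored ascending.

## Two-factor decomposition (ASCA)

The grand-mean-centered matrix is split additively:

    X_c = X_time + X_dose + X_(time×dose) + X_residual

- `X_time`: unweighted time-level means of `X_c`, expanded to samples.
- `X_dose`: unweighted dose-level means of `X_c − X_time`. Estimating dose
  *after* removing the time effect keeps the dose main effect separated
  from the interaction even when cell counts are unequal.
- `X_(time×dose)`: cell means of what remains after both main effects.
- `X_residual`: within-cell remainder.

Reconstruction is exact by construction (machine precision). For balanced
designs the four blocks are mutually orthogonal and the squared Frobenius
norms (SSQ) coincide with textbook two-way ANOVA sums of squares; for
unbalanced designs (6–10 animals per cell in the emulated design) the small
loss of additivity is measured and reported (`additivity_deviation`), never
hidden. Percent contributions are `100·SSQ_block / SSQ(X_c)`. A constant
matrix yields a degenerate decomposition with undefined percents. The
decomposition operates on the normalized, centered matrix; no OSC filtering
is applied before it (OSC belongs to the supervised branch), though
filtered input can be passed explicitly for sensitivity analysis.

**Permutation significance.** For a main factor, that factor's labels are
shuffled across samples while the other factor's labels stay attached to
their samples, and the factor's SSQ is re-estimated under the same
estimator; for the interaction, the (time, dose) label pairs are shuffled
jointly. With `n` permutations, `p = (#{SSQ* ≥ SSQ} + 1)/(n + 1)`, so the
smallest attainable p is `1/(n+1)`. Under a complete null this scheme is
exact (label exchangeability), which the test suite verifies by a KS
uniformity check over 200 null cohorts. When a true main effect is present,
the interaction's permutation null absorbs part of that main effect, making
the interaction test conservative rather than anti-conservative.

**Per-block PCA.** Each effect block is analyzed by SVD; component signs
are fixed (largest-magnitude loading positive) for determinism. Explained
variance per component is its share of the block SSQ. Interaction-score
profiles are cell means of the first component score, ordered by time
within dose — because scores are constant within a cell, cell means of
scores equal scores of cell means.

**Interaction subset search.** Every combination of `k` time levels
(k = 3…5) and `h` dose levels (h = 2…5) is re-decomposed from scratch and
its interaction contribution and permutation p recorded. On a 5×5 design
this is (C(5,3)+C(5,4)+C(5,5)) × (C(5,2)+C(5,3)+C(5,4)+C(5,5)) = 16 × 26 =
416 combinations. Combinations with an empty cell are skipped and logged.
No multiplicity correction is applied across combinations by default (the
search is exploratory and records raw p-values); an FDR column can be added
downstream. Note the denominator caveat: contributions are relative to each
subset's own total SSQ, so subsets that exclude high-variance time levels
get a mild boost — ranking by contribution is a screen, not a test.

## OSC-filtered PLS-DA

**Scaling.** Columns are mean-centered and optionally scaled: unit variance
(default) or Pareto (divide by √sd). During cross-validation scaling
statistics come from training folds only. Constant columns are left
unscaled (they are zero after centering) with a warning.

**OSC.** The orthogonal signal correction filter removes components of
X-variation orthogonal to the class-indicator matrix: starting from the
leading principal component score, alternate projection out of the class
column space and regression back onto X until the score stabilizes, then
deflate the converged orthogonal score and its loading. One component is
removed by default; the stored weights/loadings reproduce the filtered
training matrix exactly and filter new samples consistently.

**PLS-DA.** Classes are one-hot coded and centered; components are
extracted by NIPALS (scikit-learn's implementation stands behind the
component extraction). R²Y is the fraction of centered-Y variance explained
(reported in percent); predicted class is the argmax of predicted Y.

**Q².** Stratified k-fold (default 7) cross-validation;
`Q² = 1 − PRESS/SS` on the centered class matrix, with class means and
scaling refit per training fold. If the smallest class has fewer members
than the fold count, folds are reduced so every class appears in every
training fold. An automatic component count is available: A grows while the
Q² gain is ≥ 0.01.

**Permutation validation.** Class labels are permuted (default 200 times);
for each permutation R² and Q² are recomputed, and both are regressed on
the absolute correlation between the permuted and original centered class
matrices, including the unpermuted model at correlation 1. The intercepts
at zero correlation estimate the chance-fit baseline; a robust model has a
negative Q² intercept.

*Protocol choice:* the OSC filter is fit once per dataset and the
permutation test runs on the filtered matrix — the workflow of the standard
chemometrics software this mirrors. Refitting OSC on every permuted
labeling (`permutation_validate(..., n_osc>0)`) is available; it raises the
permuted Q² cloud and pushes the intercept positive even on strongly
informative data, so its intercepts are not comparable to the fit-once
convention. Because the intercept sign alone cannot distinguish signal from
noise (on null data the permuted cloud and the original model coincide, and
the extrapolated intercept is negative about half the time), the reported
per-dataset verdict (`overall_verdict`) requires R² > 50 %, Q² > 0.4 *and*
a negative Q² intercept. The null-guard test shows this combined verdict
fires on ≤10 % of signal-free cohorts even with OSC in the pipeline.

**Hotelling ellipse.** For a two-component score plot the 1−α confidence
ellipse has squared semi-axes `eig(cov) · 2(n−1)/(n−2) · F_{1−α}(2, n−2)`
around the score centroid; α → 1 collapses it to a point, singular
covariance is an error.

**VIP.** `VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)` with
`SSY_a = ‖t_a‖²‖q_a‖²`; the mean squared VIP over features is exactly 1,
and VIP > 1 is the default candidate threshold.

## Discriminant statistics

Candidates (VIP ≥ 1, or |loading| above a user threshold for the
decomposition branch) are screened per bucket by the Kruskal–Wallis test
(midrank ties, χ² p on g−1 df). Only when the screen passes at 0.05 are
pairwise comparisons of each treated group against the reference computed —
Dunn's rank z-test on the pooled ranking by default (pairwise Mann–Whitney
selectable) — with Benjamini–Hochberg correction by default (Bonferroni and
Holm selectable), applied within the family of reference-vs-group
comparisons per feature. Direction signs (+/−, group mean vs reference
mean) are reported only for comparisons significant after correction.
Bucket records aggregate to metabolite rows via the annotation map's ppm
intervals; buckets in no interval are reported as `unassigned d lo-hi`, and
conflicting signs within a metabolite are kept and flagged rather than
averaged away.

## Sub-network extraction

The metabolic network is a directed bipartite graph (metabolite → reaction
→ metabolite). The lightest path between two biomarkers charges each
traversed node on entry: metabolite nodes cost their network degree by
default (steering paths around ubiquitous cofactors), reaction nodes cost
1; an unweighted mode charges 1 per arc. Side compounds (editable list; a
common-cofactor default is provided) are never traversed as intermediates
but may be endpoints. Equal-weight paths are ordered lexicographically on
their node-id sequence — prefix order is preserved under extension, so a
Dijkstra on (weight, sequence) keys settles each node optimally and results
are deterministic. The union sub-network collects all reachable pairs'
paths with per-node provenance; unreachable pairs are reported, not raised.

## Synthetic cohorts

The generator emulates a 5-dose × 5-time destructive-sampling design with
6–10 animals per cell (unbalanced, seeded), ~30 metabolites each owning 1–4
disjoint bucket resonances with random relative weights. Effects act on the
natural-log concentration scale (multiplicative on intensities, which keeps
concentrations positive and matches the lognormal character of NMR bucket
noise): per-metabolite time trajectories are seeded low-order polynomials,
dose responses are monotone or U-shaped (non-monotone dose–response
mimicry), interactions are double-centered cell grids — optionally confined
to a time × dose block, in which case the block is resampled until no row
or column is degenerate, so every selected cell is genuinely perturbed.
Zero-sum constraints hold exactly on the log scale, so the additive
decomposition of the noise-free log matrix is exact. Noise is i.i.d.
lognormal per metabolite and sample (default σ = 0.1; an additive intensity
floor is available, default off). Bucket mapping adds a constant 1e-3
spectral floor, and rows are total-area normalized.

**Ground-truth shares.** `true_shares` are the percent contributions of the
noise-free, mapped, normalized matrix — the estimand at σ = 0. Because
noise inflates every estimated block, `expected_shares()` adds to each
block's SSQ its ANOVA degrees of freedom times the per-entry noise variance
(delta-method on the normalized scale, including the closure term from
dividing by a noisy row total), and `N−1` times that variance to the total.
This first-order corrected expectation is what a noisy realization should
reproduce; at σ = 0.05 the decomposition recovers it to well under 2
percentage points averaged over seeds.

What the generator does **not** emulate: realistic lineshapes and peak
overlap, chemical-shift drift, baseline artifacts, correlated
metabolite–metabolite physiology, litter effects, or missing samples.
Passing tests therefore establish the correctness and calibration of the
estimators under the stated generative model, not robustness to every
failure mode of instrument data.

## Problem sizes and numerical choices

Test and acceptance runs use compact grids (100–300 buckets, 12–20
metabolites) and the full 5×5 design; permutation counts are 199 for
calibration batches (200 cohorts), 999 for subset searches and 10,000 for
single-dataset inference via the CLI. p-values always use the +1
correction. Tolerances: reconstruction < 1e-9 relative; percent sums to
100 ± 0.01; VIP identity to 1e-9; ppm arithmetic to 1e-6. Determinism:
every stochastic routine takes a seed; SVD signs are fixed; subset records
and network outputs are canonically ordered.

## Known limitations

- The deposited bucket matrices of the motivating study are not
  redistributable here; the check against their published percentages runs
  only when a user supplies the tables under `data/deposited/`.
- The unweighted-level-means estimator loses exact block orthogonality on
  unbalanced designs; the deviation is reported but not corrected (no
  GLM-based generalization is implemented).
- The interaction permutation test is conservative in the presence of
  strong main effects (see above).
- Subset-search contributions are not comparable across subsets with very
  different total variance; use the permutation p together with the
  contribution.
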