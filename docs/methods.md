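# Methods

This note documents the statistical models, the synthetic-data
assumptions, the numerical choices, and the known limitations of
`methscreen`. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Signal model and per-window estimation

MBD capture enriches methylated fragments; after hybridization the
per-probe log2 Cy5/Cy3 ratio grows with the amount of methylated-CpG
mass the probe interrogates. We model the expected ratio as a strictly
increasing function of `m × w`, where `m` is the window's methylation
proportion and `w` is the coupled CpG mass: each CpG contributes weight
1 if it lies inside the probe span and a linearly decaying weight over
a 100-nt flank (a CpG half a flank beyond the edge contributes 0.5, a
full flank contributes 0). Distances outside the span are measured
from the nearest interior base, so a CpG exactly one flank beyond
either edge has weight 0.

The estimator forms, per window and sample, a posterior over a uniform
methylation grid (step 0.01, uniform prior) with Gaussian observation
noise around `link(m·w)`, and reports the **mode** — the summary the
downstream screen consumes. Numerical choices:

* log-likelihoods are max-shifted before exponentiation; the posterior
  is normalized to 1 (tested to 1e-9);
* exact ties in the posterior resolve to the lowest grid point
  (deterministic argmax);
* windows with `w = 0` are non-identifiable: flat posterior, mode
  reported at the grid midpoint 0.5, `uninformative` flag set, and the
  window is excluded from all differential testing;
* the observation SD defaults to 0.1 (the generator's probe-noise
  scale) and is a parameter; it is not estimated from the data by
  default because with one probe per window there is no within-window
  replication to estimate it from.

The synthetic forward model uses a saturating-exponential link
`floor + scale·(1 − exp(−rate·m·w))` with scale 3.0, rate 0.25,
floor 0, chosen so that typical promoter windows (≈6 CpGs) traverse
roughly two log2 units between unmethylated and fully methylated —
the dynamic range enrichment arrays typically show — while remaining
analytically invertible for oracle tests. The link parameters travel
with the simulated probe table (JSON metadata), which is what makes the
round-trip tests possible; any monotone link supplied the same way
works. The full Bayesian deconvolution this step stands in for also
couples neighbouring windows and samples the posterior; we deliberately
estimate per-window only, because only the per-window mode is consumed
downstream.

## The composite DMR screen

Samples sit in four ordinal phenotype groups (1 = lowest). The screen
is a conjunction of four criteria evaluated per 100-nt window; all four
must hold. Design choices where the procedure was genuinely open:

* **"Robust" trend test.** Implemented as OLS of methylation on the
  ordinal group score (1–4) with HC3 sandwich standard errors and a t
  reference (df = n − 2) — robustness here means heteroscedasticity
  correction, not outlier resistance. A Huber M-estimator
  (`method="huber"`) is available as an alternative for outlier-heavy
  data. A zero-variance window is degenerate: P = 1, never a DMR. A
  perfect noise-free fit has zero sandwich variance; P is set to 0 in
  that limit.
* **Mann–Whitney sidedness.** Two-sided throughout (the conservative
  default). Exact p by the full rank-configuration distribution for
  untied samples with n ≤ 20; mid-rank normal approximation with tie
  and continuity correction otherwise (ties are logged). The bulk
  screening path precomputes the exact two-sided p as a lookup table
  indexed by U for each group-size pair and is tested for exact
  agreement with both the per-pair implementation and a brute-force
  enumeration oracle.
* **MethOR direction.** Defined as odds(group-1 mean)/odds(group-4
  mean) with means clamped to [1e-6, 1−1e-6]. The bounds 0.667 = 1/1.5
  are symmetric, so the direction convention cannot change a call
  (tested via the group-relabeling symmetry property).
* **No multiplicity correction inside the screen.** The four raw
  thresholds act as a deliberately stringent joint filter for gene
  prioritisation; a BH-adjusted column for the trend p is emitted for
  information only.

Empirical calibration of the HC3 trend test at n = 24 (6/6/6/6) is
checked by simulation in the test suite: the fraction of null windows
with p ≤ 0.02 must lie within three binomial standard errors of 0.02
over 10,000 windows. The composite false-call rate under the null is
far smaller because the abs-difference criterion (≥ 0.20 at
within-group noise SD 0.03) is essentially never met by chance.

## ROI aggregation and enrichment

The 2×2 probability is the hypergeometric point mass of the table given
its margins, computed via log-gamma for overflow safety; an exact
big-integer `Fraction` mode exists for small tables and is the oracle
in tests. Interpretation choices:

* `b` and `d` count windows **outside** the ROI (not "the entire data
  set"), so the margins are consistent and `n = a + b + c + d`;
* DMROI calling uses the one-sided enrichment tail (the Fisher exact
  upper tail), with the point probability also reported;
* window significance feeding (a, c) is the trend-test p < 0.01 on
  informative windows; `use_composite=True` switches to the full DMR
  flag;
* the ROI-level Mann–Whitney operates on per-sample **means** over the
  ROI's informative windows — the simplest order-preserving ROI
  summary; `window_level_mw=True` instead accepts the ROI if any member
  window passes, for sensitivity analysis;
* ROIs with zero informative windows are excluded (logged), and window
  → ROI overlap ties are broken by nearest TSS.

Gene-set enrichment is a standard upper-tail hypergeometric against the
array-design gene universe with BH across sets. The pathway-analysis
suite this replaces uses a proprietary network background, so its
published p-values are not reproducible by construction; the
generic-GMT computation is validated against an independent tail-sum
oracle instead.

## Normal scores and association models

Fisher–Yates normal scores are computed as Φ⁻¹((r − 3/8)/(n + 1/4))
on mid-ranks (Blom's approximation to expected normal order
statistics), then re-standardized so the finite scores have mean 0 and
sample SD (ddof = 1) exactly 1 — the approximation alone does not
satisfy the mean-0/SD-1 contract, which is why the explicit
re-standardization step exists. Ties are mid-ranked **before**
standardization; missing values propagate as NaN; a constant vector is
rejected. Scores are computed once per CpG on all its non-missing
measurements and are not re-standardized within each model's complete
cases, so β remains "per SD of the measured distribution" even as
covariate missingness varies n.

Association models are OLS with intercept, one predictor CpG per model
(matching the one-row-per-CpG presentation of validation tables), with
t-based 95% CIs and two-sided p, at three cumulative covariate tiers
(sex; sex + maternal score; extended). Listwise deletion per model;
≥ 10 complete cases required; exact collinearity is detected by rank
and reported with the offending column. Robust standard errors are
deliberately **not** used at this stage — the heteroscedasticity
concern belongs to the array screen. `variance_explained` is the plain
R² of a multivariate fit. No adjustment across the CpG panel (a BH
column is informational).

## What the synthetic generator emulates — and what it does not

Array stage: per-region baseline methylation ~ Beta(2, 2) (capture is
biased toward methylated CpG-rich promoters; mid-range baselines keep
the planted ±effect/2 inside [0, 1]), shared across groups; planted
regions add monotone group offsets summing to `dmr_effect` (default
0.25) between the extreme groups; i.i.d. Gaussian within-group noise
(default SD 0.03); values clamped to [0, 1] with the clamped fraction
reported and configs clamping > 10% rejected. Planted-region baselines
are resampled into [effect/2, 1 − effect/2] so that the planted
extreme-group difference is exactly the nominal effect — otherwise the
generator's own truth labels would be wrong. Group sizes default to
6/6/6/6 (the screen design gives the total, 24, but not the per-band
split; equal bands are the neutral choice and are configurable).
Effect direction is hypermethylated-with-higher-phenotype, matching the
validated locus; the screen itself is direction-symmetric.

Validation stage: nine CpG percentages from a Gaussian one-factor
copula (loadings spaced so the extreme pairwise latent correlations hit
0.31 and 0.85 — pinned by setting the two largest loadings to √0.85
and the two smallest to √0.31) pushed through a skewed Beta(2, 5)
margin scaled to percent, so the raw values are non-normal and actually
exercise the normal-score transform. The outcome is
`100 + β·z_causal + 1.5·(sex − ½) + 0.2·(maternal − 100) + ε`, with
β = 3.2 per SD at the causal CpG (CpG2) and ε ~ N(0, 10²); the residual
SD 10 was chosen so the CpG + sex + maternal model explains roughly
16% of outcome variance in the headline scenario, the neighbourhood of
the motivating analysis. Covariates are mutually independent of the
CpG factor by default; a dedicated confounded construction is used in
the test that checks adjustment moves β toward the direct effect.

Not emulated: raw array images and dye effects, bisulphite conversion
error, cellular heterogeneity of cord tissue, linkage between the array
and validation stages (the two cohorts are drawn independently), batch
structure, and missingness mechanisms other than MCAR introduced by the
caller. Passing recovery tests therefore demonstrates correctness of
the statistical machinery under the stated model, not robustness to
those real-data features.

## Problem sizes and determinism

Default analysis/test problem sizes: 5,000 windows for null screen
calibration, 200 planted replicates for power, 500 simulated validation
cohorts (n = 175) for recovery/coverage and 1,000 for type-I error,
1,000 windows × 24 samples for the estimator round trip — sizes at
which the binomial/Monte-Carlo error of each check is comfortably
below its acceptance margin. All generators take a single integer
seed; sub-seeds are derived arithmetically and kept below 2³¹. The
pipeline writes floats with a fixed format and records sha256 of every
artifact, and a rerun with the same config and seed is byte-identical.

## Known limitations

* One probe per window: no within-window replication, so the
  observation SD is a parameter, not an estimate, and the posterior is
  only as calibrated as that choice.
* The grid posterior ignores cross-window correlation; fragment-size
  smoothing of real capture data would correlate adjacent windows and
  make the effective number of independent tests smaller than the
  window count.
* Exact Mann–Whitney p-values require untied data; clamped methylation
  values at 0 or 1 introduce ties and silently switch those windows to
  the corrected normal approximation (logged at debug level).
* The beta-like shape of real per-sample methylation frequency
  distributions is a descriptive observation, not a QC gate; a
  diagnostic histogram is easy to produce from the estimates table, but
  no filter is applied.
* With 4 ordinal groups of 6 the smallest attainable two-sided exact
  Mann–Whitney p is 2/924 ≈ 0.0022 (1 vs 4) — p-value granularity, not
  a bug, and the reason the screen's thresholds are as loose as they
  are.
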