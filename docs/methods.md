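# Methods

This note documents the statistical models behind `socgeo`, the
conventions the implementation commits to, and what the synthetic-data
generator does and does not emulate.

## The survey design

All defaults describe a 5 km × 8 km arid-land survey sampled on a
closed regular lattice with 500 m spacing: 11 × 17 = 187 locations,
each sampled in four 10-cm depth layers (0–10, 10–20, 20–30, 30–40 cm),
748 records in all. Coordinates are planar metres with the origin at
the south-west corner; y increases northward. "Closed" means boundary
nodes belong to the lattice, which is what makes the node count 187
rather than 160; the same closed-boundary rule applies to the
re-sampling sub-rectangles, so lattice points on a shared edge count in
every adjacent placement.

## Synthetic surveys

The generator draws, per layer,

    SOC(x) = exp( μ_ln + t·(y − ȳ) + σ_ln·( √(1−ν)·S(x) + √ν·ε(x) ) )

* `S` — zero-mean, unit-variance Gaussian random field with isotropic
  exponential correlation `exp(−3h/A)`, drawn by exact Cholesky
  factorization of the 187 × 187 node correlation matrix (with a ≤1e−8
  jitter fallback). At desk scale this is exact; no spectral or
  turning-bands approximation is involved.
* `ν ∈ [0,1]` — nugget fraction: the share of the log-scale sill that
  is spatially unstructured white noise (`ε`). It absorbs measurement
  error and sub-500-m variability, including composite-sampling noise.
* `A` — *effective* range in metres: the lag at which correlation has
  decayed to ≈5 % of the sill. The fitting module uses the same
  convention (`γ_exp(h) = C₀ + C(1 − e^{−3h/A})`), so
  generate → estimate → fit round-trips are self-consistent. The raw
  distance parameter (A/3 for exponential, A/√3 for Gaussian) is stored
  alongside.
* `μ_ln, σ_ln` — moment-matched so the marginal arithmetic mean and CV
  equal their targets: `σ_ln² = ln(1+c²)`, `μ_ln = ln m − σ_ln²/2`.
  Alternatively `sill_ln` pins `σ_ln²` directly (then the CV is implied).
* `t` — optional linear south→north trend on the log scale (per metre;
  default 0; negative values reproduce a northward decline for map
  demonstrations).

Default per-layer parameters are the emulated survey's own summary
statistics: SOC means 1.6/1.5/1.4/1.4 g kg⁻¹ with CVs
36.8/38.5/41.0/42.1 %, nugget ratios 0.018–0.054, effective ranges
1047–1347 m. The marginal CV and the structural sill are mutually
inconsistent in the source summaries (ln(1+0.368²)=0.127 vs 0.1048 for
the surface layer); the generator resolves this in favour of the
marginals by default and accepts an explicit `sill_ln` when the spatial
structure must be pinned instead.

Covariates (stones, sand, silt, clay, bulk density) are linear blends
`w·S + √(1−w²)·η` mapped affinely to their target mean/CV and clipped
to physical ranges, with texture triples rescaled where they would
exceed 100 %. The blend weight is the target Pearson correlation with
SOC *divided by* the attenuation induced by exponentiating the latent
field (`corr(X, e^{σX}) = σ/√(e^{σ²}−1)`) and by the nugget share
(√(1−ν)), so achieved correlations with SOC itself land on target
(verified to ±0.05 over seeds). Because stones, silt and clay have CVs
near or above 100 %, clipping at zero affects ~10 % of their values;
this is inherent to the clipped-Gaussian marginal choice (simpler than
logit/log marginals), is monitored with a warning, and measurably
distorts those covariates' upper moments but not the correlation
targets within tolerance. The 30–40 cm bulk density defaults to the
surveyed 0.5 g cm⁻³ so the stock arithmetic mirrors the survey's own
worked numbers, anomalous as that value looks.

What the generator does *not* emulate: anisotropy, cross-layer
correlation (layers are independent), non-stationary variance,
conditional simulation on real observations, and within-location
compositing (only composite values exist). Tests passing on these
fields therefore demonstrate correctness of the estimators under a
stationary isotropic log-normal model, not robustness to real-world
violations of it.

## Descriptive statistics

SD uses the n−1 denominator; skewness and kurtosis are the
small-sample-adjusted estimators with kurtosis reported as excess; CV
is in percent. Normality is checked with the one-sample K-S test
against a normal with estimated mean/SD and the asymptotic p — the
classical desktop-package procedure. With estimated parameters this p
is anticonservative (the Lilliefors issue); a corrected `lilliefors=True`
option is provided, but the plain test is the default for fidelity to
standard practice. The log-transform rule flags a variable when raw
p ≤ 0.05 and ln-scale p > 0.05. Depth-layer means are separated by
one-way ANOVA plus pairwise LSD t-tests on the pooled error mean
square, summarised by the insert-and-absorb compact-letter-display
algorithm with letters assigned down the descending-mean order.
Constant samples report skewness and kurtosis of 0 by convention.

## CV–area scaling and sample-size planning

Sub-rectangles with whole-km sides (w ≤ W, h ≤ H) give W·H "methods";
methods sharing w·h form one distinct area (24 of them for 5 × 8). For
each integer-km placement of each method the CV of the enclosed SOC
values is computed, and all placements of all same-area methods are
pooled with equal weight — not averaged per-method first. Placements
with fewer than two points are dropped with a warning. The curve is
summarised by OLS of ln CV on ln area (`CV = a·A^b`), excluding
non-positive CVs; at the full area the curve equals the whole-sample CV
exactly (single placement). The planner

    NRS = ⌈ (z_{1−α/2} · CV / Δ)² ⌉

uses the standard-normal quantile rather than a finite-df t because n
is unknown a priori, and ceiling rounding because NRS is a minimum;
with CV(1 km²) = 26.7 % and b = 0.0789 this reproduces 110/227/326
samples at 1/100/1000 km² (Δ = 5 %, 95 % confidence).

## Semivariograms and model fitting

γ̂(h) = Σ(z_i − z_j)²/(2N(h)) over pairs with separation in
((k−1)·w, k·w]; bins run to ⌊max_dist/w⌋, so the defaults (w = 500 m,
max 4700 m) give nine intervals. The reported lag per bin is the mean
pair separation; empty bins are dropped. Analysis runs on ln SOC by
default — the raw marginals are strongly right-skewed and the
structural sills of interest (≈0.10–0.15) live on the log scale — with
a raw-scale mode available. Directional variograms (azimuth clockwise
from north, angular tolerance) serve as the anisotropy/trend
diagnostic; a 90° tolerance reproduces the omnidirectional estimate.

Four families are supported — exponential, spherical, Gaussian
(effective-range parameterization) and linear — fitted by weighted
least squares with pair-count weights N(h) (Cressie's N/γ² available).
Bounded families use multi-start trust-region optimization (8 starts
spanning the lag span) under C₀ ≥ 0, C ≥ 0, A ∈ (0, 2·max_dist]; the
linear family is a non-negative least-squares problem solved exactly.
Model selection ranks by weighted RSS, ties broken by R², then by
parameter count. The nugget-to-sill ratio classifies spatial
dependence: <0.25 strong, 0.25–0.75 moderate, >0.75 weak.

**Range identifiability.** With 187 points and nine lag bins the WLS
range estimator is strongly right-skewed: in a minority of realizations
the weighted RSS keeps decreasing in A and the global optimum sits at
the bound, so the *mean* fitted range across simulated surveys exceeds
the generating value by a wide margin even though the median is close
(the acceptance checks compute both the distribution and its mean).
This is a sampling-distribution property of the estimator at this
design size, not an optimizer defect: the fitted optima match a dense
grid-search oracle. Users comparing fitted ranges across surveys of
this size should prefer medians or inspect the RSS profile in A before
trusting a large fitted range.

## Ordinary kriging and validation

Predictions solve the standard semivariance system
`[Γ 1; 1ᵀ 0][λ; μ] = [γ₀; 1]` globally (all samples; exact at desk
scale), giving Ẑ(x₀) = Σλᵢz(xᵢ) with Σλᵢ = 1 and kriging variance
σ² = Σλᵢγ(xᵢ,x₀) + μ, clamped at zero with a warning if numerically
negative. γ(0) = 0 exactly at zero lag (the nugget is a right limit),
which makes kriging an exact interpolator when C₀ = 0. Duplicate
sample locations raise an error rather than silently regularizing.
Leave-one-out cross-validation (each point predicted from the others,
then replaced) reports ME (bias, should be ≈0), RMSE, and RMSSE
(standardized errors; ≈1 when the variogram's variance model is
calibrated — verified at 0.9–1.1 on average under the generating
model). Maps are kriged on a regular grid and written as ESRI ASCII
rasters; when the analysis ran on ln SOC the back-transform default is
the lognormal-kriging correction `exp(ŷ + σ²/2 − μ)` (μ the Lagrange
multiplier), with naive `exp(ŷ)` as an option — the output records
which rule was applied, since the two differ visibly away from samples.

## Correlations, stepwise regression, stocks

Pearson matrices are pairwise-complete with two-sided t-test p-values;
zero-variance inputs yield flagged NaNs. Stepwise regression is
forward selection by smallest partial-F p (entry at p ≤ 0.05) with
backward elimination (removal at p > 0.10) — the classical desktop
defaults — skipping candidates that would make the design numerically
collinear. Explained variance is reported as sequential R² increments
at entry (summing to the final unadjusted R²), alongside adjusted R²
and MSE. Regression runs on raw SOC by default; the analysis scale is
the caller's choice.

Stocks follow `SOCD_i = 0.01·SOC_i·BD_i·d_i·(1 − CF_i/100)` kg C m⁻²,
cumulated over layers and multiplied by area. The coarse-fragment
correction defaults to on, but the pipeline reports densities both
ways: surveyed bulk densities are sometimes whole-soil values with the
stone effect already embedded, in which case applying CF double-counts
it — the printed pair makes the choice auditable. Per-location
densities are averaged within layers (mean of densities, not density
of means); a means-only mode covers summary-table inputs.

## Problem sizes and determinism

All stochastic calibration checks run on the full 187-node design:
200 realizations for variogram-parameter recovery, 500 for marginal-CV
calibration, 100 for cross-validation calibration — sizes at which the
Monte-Carlo standard errors are comfortably inside the stated
tolerances while the whole suite completes in about a minute. Every
stochastic path takes an explicit seed; multi-layer and multi-stage
runs derive per-layer/per-stage substreams with `SeedSequence.spawn`,
so identical seeds give bit-identical tables and reports.

## Known limitations

* Isotropic models only are fitted (directional variograms are
  diagnostic); no universal or co-kriging; no conditional simulation.
* The K-S default is anticonservative by construction (see above).
* Fitted ranges from single ~190-point surveys are heavy-tailed; see
  the range-identifiability note.
* Clipped-Gaussian covariates misrepresent the marginal shape of
  very-high-CV variables (stones, silt, clay) even though their
  correlation targets are met.
* No depth extrapolation below the deepest sampled layer.
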