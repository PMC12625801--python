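# Methods

## Model

Across species, body mass and femoral dimensions are related by a power
law, linear on the natural-log scale:

    ln(BM) = β₀ + β₁ ln(FCSA) + ε

with BM internally in grams and FCSA (femoral cortical cross-sectional
area) in mm². Trait tables carry mass in kg at every interface; the
gram/kg conversion happens inside the fitting and prediction code so that
an intercept near 3.5 corresponds to the conventional gram-scale
reporting of primate allometries.

Residuals are not independent: related species inherit deviations from
the allometric line from shared ancestors. The residual covariance is
modeled as σ²·V(λ), where C is the phylogenetic variance–covariance
matrix of the species in the fit — C[i,j] is the branch length shared
from the root to the most recent common ancestor of i and j, C[i,i] the
root-to-tip depth — and V(λ) multiplies the off-diagonal of C by Pagel's
λ ∈ [0, 1]. λ = 0 collapses to ordinary least squares (star phylogeny);
λ = 1 is full Brownian-motion covariance, under which the PGLS slope
equals the independent-contrasts through-origin slope (asserted in the
test suite against a Felsenstein-pruning oracle).

Three candidate models are supported: mass on FCSA, on femoral length
(FL, mm), and on both. Candidates are ranked by AIC with parameter count
k = p + 2 (regression coefficients plus σ² and λ); near-ties (ΔAIC < 2)
prefer the model with fewer parameters. AIC here is a within-run ranking
device — likelihood constants differ across software, so these values are
not comparable to AICs computed elsewhere.

## Estimation

GLS is solved by Cholesky whitening: with V = LLᵀ, ordinary least squares
on L⁻¹X, L⁻¹y gives β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y. λ̂ maximizes the profile
log-likelihood (β and σ² concentrated out, ML denominator n) over [0, 1]
by bounded scalar minimization to an absolute tolerance of 1e-8; both
endpoints are always evaluated so boundary maxima are never missed, and
the optimizer is verified against grid searches (101- and 1001-point) in
the tests. On a star tree the profile is flat; the convention is λ̂ = 0
with an explicit flag. σ̂² is reported with the n − p denominator for
inference (coefficient SEs, t and F statistics, prediction variances) and
enters the likelihood with the ML denominator.

R² is defined on the whitened scale (1 − RSS_w/RSS_w,intercept-only, both
under V(λ̂)), with adjusted R² = 1 − (1 − R²)(n − 1)/(n − p); at λ = 0
this reduces to the classical OLS value. Because conventions differ, the
classical raw-residual R² and its F statistic are also carried on the fit
object (`r2_raw`, `fstat_raw`).

## Prediction intervals

For a new specimen with design row x₀, the default ("independent") mode
treats the specimen as phylogenetically uncorrelated with the reference
sample:

    Var = σ̂²·d₀ + x₀ᵀ cov(β̂) x₀

with d₀ the mean extant diagonal of V(λ̂) (the standardized tip depth; 1
on a unit-depth ultrametric tree). Limits are exp(point ± t₀.₉₇₅,n−p·SE),
symmetric on the log scale and hence multiplicative in kg
(upper/estimate = estimate/lower). No log-normal back-transform bias
correction is applied, matching the convention of reporting the median of
the predictive distribution. Interval width grows with leverage
|ln(FCSA) − mean reference ln(FCSA)|, so extrapolated giants get wider
intervals.

The "blup" mode exploits a fossil's known placement on the tree: with c
the λ̂-scaled covariance vector between the fossil tip and the reference
tips and d its depth, the point estimate gains the best-linear-unbiased-
prediction term cᵀV⁻¹(y − Xβ̂) and the variance becomes

    σ̂²·(d − cᵀV⁻¹c + uᵀ(XᵀV⁻¹X)⁻¹u),   u = x₀ − XᵀV⁻¹c

which reduces exactly to the independent mode when c = 0. Each specimen
is predicted marginally; fossil–fossil covariance is ignored.

A prediction SE below 1e-9 (numerically exact fit) is snapped to zero and
the interval degenerates to the point.

## Aggregation and comparisons

Specimen predictions are pooled into species means with equal weight per
specimen; this equals the specimen-count-weighted combination of
per-source means, which is what "weighted mean" means here. Pooling the
127 packaged specimen estimates reproduces the published species table:
mass and FCSA means to two decimals everywhere, prediction-limit means to
within 0.01 kg (the published means were computed from unrounded
specimen values, so rounding of the printed inputs can propagate an extra
half-unit).

Cross-study comparisons are paired two-sided t-tests on natural-log
masses, dropping incomplete pairs. Masses across these taxa span two
orders of magnitude and differences are multiplicative, so the log scale
is the appropriate pairing; it is also the scale on which the published
statistics (t = −13.6 and −6.5, df = 13) are reproduced — raw-scale
pairing gives roughly −4.8 and −2.2 instead. The degenerate case of a
zero-variance difference vector returns t = 0 (p = 1) rather than NaN.

## Synthetic-data generator

The extant reference dataset behind the published lemur allometry (570
individuals, 77 species) is not redistributable, so the package generates
reference data with the same statistical structure:

* **Tree** — pure-birth (Yule) tree conditioned on n extant tips, grown
  past the n-th speciation by the Exp(n·rate) waiting time so no pendant
  edge is zero, then rescaled to unit depth. Unit depth makes σ the
  residual SD per unit of independent evolution.
* **Traits** — ln(FCSA) uniform over the log of a configured range
  (default 5–1000 mm², spanning mouse-lemur-sized to gorilla-sized
  femora); ln(BM) from the allometric line plus ε drawn through the
  Cholesky factor of σ²V(λ). Defaults: slope 1.26, intercept 3.48
  (ln grams), σ = 0.37, λ = 0.64 — the fitted extant allometry. FL is
  optionally generated by inverting its own allometry (slope 2.65,
  intercept −5.19, λ = 0.88).
* **Fossils** — species grafted at random points on the tree (uniform on
  total branch length, pendant edge closing to tip depth), true masses
  drawn from the same line with residuals sampled *conditionally on the
  extant residuals* under the λ-scaled covariance of the extended tree,
  so the joint extant+fossil law is exactly the model's. Specimen FCSAs
  are jittered log-normally (SD 0.05) around the species value; fossil
  species FCSA spans 55–710 mm², the observed subfossil lemur range, so
  prediction is exercised at the same leverage.

What passing tests on this generator show: the estimator recovers its own
generating process (slope bias < 0.01 at 500 replicates; λ̂ mean within
0.1 of truth, biased low at n = 62 as ML λ̂ is known to be), and the
prediction intervals are calibrated to slightly conservative — empirical
coverage of nominal 95% intervals runs ≈ 95–97% because real (simulated)
fossils share ancestry with the reference tips, which the independent
mode deliberately ignores. What they do not show: robustness to
measurement error in the reference traits, to tree misspecification, to
non-uniform trait sampling, or to intraspecific structure beyond
log-normal jitter — all absent from the generator by design.

## Reference tables and name handling

The packaged specimen table carries each femur's published estimate;
because every published estimate lies on the fitted line, an ordinary
log-log regression across the 127 (FCSA, estimate) pairs recovers the
published coefficients to ~4 decimals (1.2606, 3.4847), far beyond their
printed 2-dp rounding — this is how fixture-based tests obtain
full-precision reference coefficients.

Tip labels and species names are matched after trimming whitespace and
normalizing underscores to spaces; a user-supplied two-column synonym map
handles genuine spelling variants (the packaged one reconciles
Palaeopropithecus/Paleopropithecus, robusta/robustus, and the
dolichobrachion variants used inconsistently across the source tables).

## Problem sizes and determinism

Default study sizes — 500 replicates for parameter recovery, 20 × 100 =
2,000 intervals for coverage, 62-tip trees — were chosen so the full
validation runs in seconds while leaving Monte-Carlo error well inside
the tolerances tested. All randomness flows from explicit integer seeds
through `numpy.random.default_rng` (trees through Python's `random` into
dendropy); identical seeds give byte-identical trees, tables, and
reports.
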