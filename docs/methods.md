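# Methods

This note documents the estimators implemented in `localsem`, the defaults
and the reasoning behind them, what the synthetic populations do and do not
emulate, and the numerical choices that matter for reproducing results.

## Model and estimands

The observed indicators follow a covariance-structure SEM,
X = ν + Λη + ε with η = Bη + ζ, so that

Σ(θ) = Λ(I − B)⁻¹ Φ (I − B)⁻ᵀ Λᵀ + Ψ.

The scientific object is not a single θ but the curve θ(a) over a
continuous moderator a (age in the motivating applications).  The mean
structure is deliberately left unmodeled: conditional means are removed
nonparametrically (below), and all estimation operates on conditional
covariance matrices.  Interest centers on whether components of θ(a) —
loadings, factor variances, the factor correlation, residual variances —
are invariant or vary with a.

## Kernel weighting and local moments

At each focal point a_t a subject receives w_nt = K((a_n − a_t)/bw).

* **Kernels.** Gaussian K(x) = exp(−x²/2), Epanechnikov and uniform.  All
  are normalized so K(0) = 1; the Epanechnikov kernel is implemented as
  (1 − x²)·1{|x| ≤ 1}, i.e. without the 3/4 density constant, because
  weighting is invariant to a constant rescaling of w and K(0) = 1 keeps
  the "full weight at the focal point" convention consistent across
  kernels.
* **Bandwidth.** bw = h·N^(−1/5)·σ_A.  Default h = 2; h = 1.1 (the classic
  density-estimation factor) is available.  Monte-Carlo comparisons of
  pointwise RMSE (which our own harness reproduces qualitatively) favor
  h = 2 over 1.1 or 3: the smaller bandwidth buys little bias reduction at
  a substantial variance cost at practical sample sizes.
* **Focal grid.** Default: 13 equidistant points spanning the 5th–95th
  moderator percentile, capped at the number of distinct values; a
  percentile-spaced grid is available.  Focal points whose weight sum W_t
  falls below 5·I are dropped with a warning — below that, an I×I
  covariance is not usefully estimable.
* **Conditional means.** Per indicator and focal point, a local quadratic
  regression in (a_n − a_t), solved by the 3×3 weighted normal equations;
  singular designs (e.g. a single support point) fall back to linear and
  then intercept-only fits.  With `residualize=False` residuals are taken
  around the plain kernel-weighted mean, never around zero — conditional
  covariances must remain central moments.
* **Conditional covariances.** Weighted mode
  σ̂_ij(a_t) = W_t⁻¹ Σ_n w_nt e_nit e_njt (denominator W_t, the ÷N-style ML
  convention, no −1 correction), or local-regression mode: the intercept of
  a local quadratic fit to the residual products.  Missing data: pairwise
  deletion with per-pair weight renormalization.
* **PD repair.** Indefinite Σ̂_t are repaired by clipping eigenvalues at
  1e−4 times the largest eigenvalue and rescaling the diagonal back to the
  input variances.  The floor is the smallest perturbation that keeps the
  ML discrepancy (which needs Σ̂_t⁻¹ implicitly through the fit) well
  defined without visibly moving estimates.  Inputs already PD relative to
  the floor are returned unchanged.

## Estimation

All fitting minimizes the weighted ML discrepancy
F(θ) = Σ_g n_g·D(S_g, Σ_g(θ)), D(S, Σ) = log|Σ| + tr(SΣ⁻¹) − log|S| − I,
with the kernel weight sums W_t as group weights in the locally weighted
case.  Because subjects enter several focal points, this is an M-estimation
objective, not a likelihood; the package therefore **never** reports
information-matrix standard errors — inference is resampling-based.

* **Pointwise mode** fits each focal point separately.
* **Joint mode** is a single constrained minimization across all focal
  points.  Cross-focal-point structure is expressed through a linear
  parameter mapping: each free model parameter is classed as
  focal-specific, invariant, or (piecewise) linear/quadratic in the grid
  index.  Polynomial classes use constant first/second-difference
  parameterizations directly (an intercept-slope(-curvature) basis over the
  scaled grid index); piecewise variants use a truncated-power spline basis
  with knots at equal-length block boundaries, which keeps curves
  continuous across segments.
* **MGM mode** discretizes the moderator (distinct values, or quantile
  bins), computes per-bin ML (÷N) covariances and fits a classical
  multiple-group model with bin sizes as weights.  On grid-valued data the
  uniform kernel with bw = Δ/2 reproduces MGM exactly, which the test suite
  exploits as an equivalence oracle.
* **DIF curves.** For parameters held invariant (and for fixed anchor
  loadings), all fitted parameters are frozen at their per-focal-point
  values and the DIF set is freed; the minimization decouples over focal
  points and is solved as one batched problem, warm-started at the
  invariant estimates.  DIF curves reuse the (possibly PD-repaired) Σ̂_t of
  the main fit.
* **Identification.** The parser fixes the first loading of each factor at
  1 unless the user fixes one explicitly; invariant loadings are an
  alternative route.  A pointwise average-loading-equals-1 constraint can
  be emulated through explicit fixed values but is not a built-in class.

### Optimizer

Quasi-Newton (L-BFGS-B) with an analytic gradient of the discrepancy,
batched across groups; up to 3 jittered restarts on non-convergence.  Start
values: free loadings 0.7, residual variances half the mean sample
variance, factor variances half the mean variance of their indicators,
covariances and regressions 0.  Variance positivity is enforced by box
bounds (1e−8) for coordinates that map one-to-one onto variances, plus a
Cholesky-failure penalty that makes the line search retreat from the
non-PD region.  A log-reparameterization of variances was rejected because
linear/quadratic cross-focal-point constraints are affine on the natural
scale and would silently change meaning under a log transform.

Convergence: projected-gradient max-norm 1e−8 on the weight-normalized
objective (F/ΣW_t) and relative objective change 1e−13.  This is tighter
than generic SEM practice on purpose: the package asserts elementwise
agreement at 1e−5 between independent routes to the same optimum
(pointwise vs joint, kernel-weighted vs multiple-group), which a 1e−6
tolerance does not reliably deliver.  Bootstrap and permutation refits are
warm-started from the original solution and run at 1e−7 — resampling noise
is orders of magnitude larger than the difference.

### Fit statistics

The χ² analogue is the weighted discrepancy sum Σ_g n_g D_g with
df = G·I(I+1)/2 − (free parameters).  RMSEA = sqrt(max(0, (χ²−df)/(df·n)))
with n = Σ_t W_t; CFI/TLI use the per-group diagonal-covariance
independence baseline (whose ML solution is diag(S_g) in closed form);
SRMR is the weighted mean across groups of the root-mean-square
correlation-metric residual (lower triangle including the diagonal);
GFI = 1 − tr[(Σ⁻¹S − I)²]/tr[(Σ⁻¹S)²], weighted across groups.  In joint
estimation n counts subjects with their kernel multiplicity, so these
statistics are approximate summaries, flagged as such, not test statistics.

## Inference

Let f̂(a_t) = W_t/Σ_s W_s be the discrete moderator density over focal
points (a documented convention — for a continuous moderator there is no
canonical discrete density) and ξ̂ the curve of one parameter.

* **Curve summaries.** M̂ = Σ f̂ θ̂, SD̂ = sqrt(Σ f̂ (θ̂ − M̂)²).  SD̂ is
  positively biased under a flat curve.
* **Bootstrap.** Nonparametric (subjects with replacement; default R = 200),
  cluster (whole clusters with replacement), or a user replication design
  (N×R weight matrix with a scale factor: 1/R for bootstrap-like, 1 or
  (R−1)/R for jackknife-like designs).  The grid, kernel and bandwidth are
  frozen at their original-fit values; moments and estimates are fully
  recomputed per replicate.  Replicates that fail to converge are dropped
  and counted; more than 20% dropped aborts.
* **Bias-corrected SD.** SD̂_bc = sqrt⁺(2·SD̂² − mean_r SD̂*²), the
  bootstrap-bias-corrected variant, with SE the replication SD of SD̂*.
  Replicate SDs use each replicate's own f̂* — they are statistics of the
  replicate dataset.
* **SD test.** t = SD̂_bc/SE against the one-sided upper normal tail
  (p = 1 − Φ(t)).  One-sided because the alternative — any variation — is
  directional in SD; SD̂_bc = 0 gives p = 0.5 by this convention.  The
  normal reference is known to be liberal: on null data at nominal 1% the
  empirical rate is around 5% (reproduced by `scripts/acceptance.py`).
  Invariance-constrained parameters have SD exactly 0 in every replicate;
  their test is reported as undefined rather than p = 0.5.
* **Wald tests.** V = c·Σ_r (ξ*_r − ξ̄*)(ξ*_r − ξ̄*)ᵀ with c the
  replication factor (1/R for bootstrap).  Equality test:
  χ² = (Hξ̂)ᵀ(HVHᵀ)⁻¹(Hξ̂) with H the (T−1)×T first-difference matrix,
  df = T−1; the statistic is invariant to the choice of full-rank contrast
  basis, and a singular HVHᵀ falls back to a pseudo-inverse with
  rank-adjusted df (warned).  Functional test: GLS regression of ξ̂ on
  polynomial moderator terms (raw powers of a_t) using V, Wald test that
  the non-intercept block vanishes.  The Wald test is conservative at
  these R and T.
* **Permutation test.** The moderator column is randomly permuted (its
  multiset preserved), the full estimation re-run, and the per-parameter
  curve SD recorded; p = (1 + #{SD* ≥ SD̂})/(B + 1) (add-one convention, so
  the minimal p is 1/(B+1)).

## Synthetic populations and what they show

`make_population` builds exact-moment populations: within each moderator
group, a multivariate normal draw is whitened and recolored so the sample
mean and (÷n) covariance *equal* their targets to machine precision.
Running the uniform-kernel/bw = Δ/2 pipeline on such a population therefore
reproduces the generating curves with zero estimation noise — the
end-to-end recovery tests separate numerical error from sampling error.

Three presets share one measurement design (one or two factors, three
indicators each, moderator 6…18 at 13 equidistant values, 10,000 subjects
per value by default):

* `dgm1` — loadings and structural parameters vary linearly with the
  moderator, residual variances invariant;
* `dgm2` — loadings and residuals invariant; factor variances and the
  factor correlation vary (variances 1 ± 0.3·u, correlation 0.4…0.75 over
  the standardized moderator u ∈ [−1, 1]);
* `dgm3` — everything invariant (the null for size experiments).

Base loadings lie in 0.55–0.8 with residual variances set for unit
indicator variance at the central moderator value.  These magnitudes are
the package's own choices, selected once as typical of published
confirmatory factor analyses in this literature; every qualitative claim
the harnesses check (consistency, SD-estimator bias ordering, test size)
depends on the invariance *structure*, not on the particular values.

What the populations do **not** emulate: non-normal indicators, missing
data, sampling weights, clustered sampling, moderator measurement error,
and mean-structure trends beyond what residualization removes.  Passing
tests therefore demonstrate correctness of the estimators and the
qualitative statistical behaviour of the tests under clean conditions, not
robustness to real-data pathologies.

## Monte-Carlo harnesses and problem sizes

`run_recovery_study` reports density-weighted absolute bias and pointwise
RMSE (wBias, wRMSE) of selected curves over replications;
`run_size_power_study` reports empirical rejection rates of the SD and Wald
tests per parameter class (factor variance, loading DIF effects, residual
variances) and pooled, with binomial Monte-Carlo standard errors.  The
package's standard configuration — and the one `scripts/acceptance.py`
runs — uses 500 replications at N = 1000 with 100 bootstrap replicates,
chosen as the point where the Monte-Carlo SE of a ~5% rate (≈1%) is small
relative to the effects of interest while a full study stays at
desk-runtime (minutes) on a single core.  Warm-started replicate fits make
this feasible: one joint fit of the one-factor model costs ~10 ms.

## Known limitations

* One moderator only; no multivariate kernels.
* Covariance structures only: no mean/threshold structures, no categorical
  indicators, no WLS or model-robust discrepancies.
* The moderated-nonlinear-factor-analysis connection is exploited only as
  the grid-valued uniform-kernel equivalence; no standalone MNFA estimator.
* Sampling weights fuse multiplicatively with kernel weights — a documented
  convention, as no canonical combination rule exists.
* Joint-estimation fit statistics inherit the pseudo-likelihood caveat
  above; treat them as descriptive effect sizes.
* The SD test's normal reference is liberal by construction; for a target
  level of 5%, test at nominal 1%.
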