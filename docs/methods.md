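# Methods

## The functional correlation

Each ROI's recorded time course is modeled as a noisy observation of a
latent random function: Y_kij = X_ki(t_j) + ε_kij, with i.i.d. measurement
error of per-ROI variance σ_k² and a common dense sampling grid
t_1 < … < t_J shared by all subjects.  The Pearson functional correlation
between ROIs k and l is

    rho_kl = E⟨X_k − μ_k, X_l − μ_l⟩ / (E‖X_k − μ_k‖² · E‖X_l − μ_l‖²)^½,

with ⟨·,·⟩ and ‖·‖ the L² inner product and norm over the time domain.
Unlike the per-subject Pearson correlation of the two series (TCC), which
centers each series on its own mean and so responds only to profile shape,
rho_kl compares the random functions themselves: subject-level amplitude
differences count.  All integrals are evaluated by composite-trapezoid
quadrature on the observed grid; the trapezoid rule is exact for the
piecewise-linear interpolant and keeps every inner product symmetric, which
in turn makes the discretized eigenproblem symmetric.  Grid mismatch
between subjects is an error, never a silent interpolation; an explicit
linear-interpolation resampler (`resample_to_grid`) is provided for
harmonizing grids deliberately.

## Multivariate FPCA estimation (dense design)

The K-variate process is expanded as X_i(t) = μ(t) + Σ_r ξ_ri (D φ_r)(t)
with D(t) = diag(v_k(t)^½) and vector eigenfunctions φ_r that are jointly
orthonormal across ROIs, Σ_k ⟨φ_kr, φ_kr'⟩ = δ_rr'.  Estimation steps:

1. **Moments.** μ̂_k(t_j) is the cross-sectional mean (a local-linear
   smooth is optional and off by default — dense designs average the noise
   out of the mean already).  The raw pointwise variance (n−1 denominator)
   equals v_k(t) + σ_k² in expectation; the noise-free variance function
   v̂_k is recovered by fitting a local-linear surface to the off-diagonal
   entries of the per-ROI sample covariance and evaluating it on the
   diagonal, where the noise does not appear.  σ̂_k² is the average gap
   between the raw and the smoothed diagonal, clipped at 0 (noise is
   assumed homoscedastic within an ROI).  v̂ is floored at 1e-10 before
   forming v̂^{−1/2} so degenerate (constant) ROIs yield finite normalized
   residuals rather than infinities.
2. **Normalized covariance.**  Z_ki(t) = v̂_k(t)^{−1/2}(Y_ki(t) − μ̂_k(t));
   the (KJ)×(KJ) sample covariance of the stacked Z has the noise ridge
   σ̂_k²/v̂_k(t_j) subtracted from the diagonal of each auto-block.
3. **Surface smoothing.**  The whole covariance matrix is smoothed by a
   tensor-product Gaussian-kernel local-linear smoother,
   (I_K ⊗ S) C (I_K ⊗ S)ᵀ.  This is essential, not cosmetic: with n = 100
   subjects and K·J ≈ 100 grid values the raw sample covariance carries a
   floor of rough, Marchenko–Pastur-type noise eigenvectors (λ̂ ≈ 0.05
   each in the simulation below).  Left in place, that floor drags the
   variance-explained truncation rule from the true L ≈ 3 up to L ≈ 15 and
   attenuates the model-based correlation by roughly −0.08; smoothing
   suppresses exactly those rough directions and restores near-unbiasedness
   (+0.01 to +0.03 in the study below).  The bandwidth is a plug-in choice
   of 0.1 × grid span for every smoother in the package (mean, covariance
   diagonal, surface, bootstrap variance curves): large enough to kill
   grid-frequency noise, small enough that the smooth kernels used here
   (curvature of order 1 over a unit domain) incur only O(h²) ≈ 1% bias.
4. **Eigenproblem.**  With W the diagonal quadrature-weight matrix (per
   ROI block), the symmetrized problem W^½ C W^½ u = λ u is solved by a
   dense symmetric eigendecomposition; eigenfunctions are mapped back by
   W^{−1/2} and renormalized so that Σ_k ⟨φ̂_kr, φ̂_kr'⟩ = δ_rr' holds
   under quadrature.  Negative eigenvalues (possible after noise
   correction) are clipped to 0 and excluded from the truncation rule's
   denominator.  Signs are fixed deterministically (largest-magnitude
   element positive); the correlation estimator is sign-invariant.  A
   Gram-matrix (duality) shortcut for n ≪ K·J is deliberately *not* used:
   the diagonal noise correction destroys the inner-product structure the
   trick relies on, and at the problem sizes this package targets (K·J of
   order a few hundred) the dense solve is cheap.  Scores are quadrature
   inner products of the unsmoothed Z against the eigenfunctions, so they
   are exactly mean-zero.
5. **Truncation.**  L is the smallest M whose leading eigenvalues exceed a
   fraction δ of the positive-eigenvalue total (strict inequality);
   δ = 0.90 by default.

Not covered (by design): sparse/irregular per-subject sampling and
conditional-expectation (PACE-style) scoring; data-driven bandwidth
selection beyond the plug-in rule.

## The four estimators

- **PFCm** — the model-based estimator (README formula), evaluated on the
  retained components.  Bounded in [−1, 1] because its numerator/denominator
  form a Gram matrix.
- **PFCo** — plug-in: expectations become cross-sectional means, integrals
  quadrature sums, observations stand in for the latent functions.  No
  noise correction, so it attenuates when σ² is non-negligible.
- **PFCu** — per-ROI univariate FPCA (the K = 1 special case of the same
  machinery, noise-corrected, per-ROI truncation at the same δ), then the
  plug-in correlation of the two reconstructed trajectory sets.  Its
  numerator is the empirical cross-covariance trace of the reconstructions,
  so unlike PFCm it shares no components across ROIs.  The underlying
  method description leaves PFCu's numerator under-determined; this
  reconstruction-based reading is one defensible choice, kept isolated
  behind the function boundary.  Note it still consumes the empirical
  cross-dependence of the reconstructions, which makes it a stronger
  competitor than a construction that pairs per-ROI components blindly.
- **TCC** — per-subject Pearson correlation of the two series, averaged
  over subjects.  Subjects with a constant series are dropped from affected
  pairs with a warning.

Degenerate pairs (no retained variation) become NaN entries in a
connectivity matrix rather than aborting it; the pairwise functions raise
`DegenerateCorrelationError` instead.

## Two-group inference

Observed differences U_kl = r²_kl − r¹_kl come from separate per-group
fits.  The null distribution is a pooled bootstrap (B = 1000 by default):
fit the mFPCA once on the pooled n = n₁ + n₂ subjects, retain M components
by the δ rule, then per replicate resample n subject indices with
replacement, assign the first n₁ to group 1 and the rest to group 2 (so
both groups are drawn from the pooled distribution — this imposes the
null while preserving within-subject dependence), and re-estimate per
group only the cheap ingredients: eigenvalues as sample variances of the
resampled scores and variance functions as local-linear smooths of the
group's mean squared residuals about its own group mean (the smoother is
precomputed as a hat matrix, so each replicate costs a few matrix-vector
products).  The group-specific mean (rather than the pooled mean) is used
for those residuals, matching the group-specific eigenvalues.  The p-value
of a pair is the fraction of replicates with |U^b| > |U| — no add-one
correction, so p = 0 is attainable (an optional add-one variant is not
provided; the granularity 1/B is documented behavior).  Replicate b draws
from the deterministic substream seeded by (seed, b), so results are
reproducible and order-independent.

**Adaptive FDR step-up.**  With ordered p-values P_(1) ≤ … ≤ P_(m) and
H = Σ_{j≤m} 1/j, define q(m₀) = max{q : P_(q) ≤ (q/m₀)·α/H} (0 if none);
the estimated number of true nulls is m̂₀ = max{L ≥ 1 : L ≤ m − q(L)},
floored at 1 when no L qualifies (the fixed-point definitions are otherwise
undefined in degenerate cases); Q = q(m̂₀) smallest p-values are rejected,
ties broken by stable original order.  The harmonic factor H is the
standard dependence penalty; dropping it and forcing m̂₀ = m recovers the
classic Benjamini–Hochberg procedure (verified against statsmodels in the
test suite).  Reported "adjusted p-values" are the Benjamini–Yekutieli-style
step-up-consistent values min_{q'≥q} min(1, m·H·P_(q')/q'); they are a
reporting convenience derived from the rejection rule, not an input to it.

**Mean tests.**  The two-sample mean-function tests (e.g. a sex effect
within an age group) use pooled-fit mFPC scores as finite-dimensional
proxies: the classical Hotelling T² with its F transform
(L, n_A + n_B − L − 1), and a distribution-free bootstrap version that
resamples subjects from the pooled score sample.  The exact statistic of
such score-based tests is a modeling choice; the Hotelling-type quadratic
form is used for both the observed and the bootstrap statistics.

## The synthetic-data generator

The generator emulates the study conditions of the estimator comparison: a
bivariate process on 51 equally spaced points spanning [0, 1] (inclusive
endpoints, spacing 0.02), n = 100 subjects, mean functions
μ(t) = (t − 2.25, cos t), variance functions v(t) = (1.25, t + 5), noise
variances σ² = (1, 4), and marginal correlation kernels J₀(a·d) (Bessel,
ROI 1) and Matérn with smoothness ν and unit range (ROI 2); kernel
parameters (a, ν) are (1, 1) in scenario 1 and (0.8, 0.75) in scenario 2,
the first printed element mapping to the Bessel parameter and the second to
the Matérn smoothness.  The cross-covariance block is

    C₁₂ = γ · C₁₁^½ C₂₂^½,   |γ| ≤ 1  (default 0.5),

with operator square roots taken in the quadrature-weighted space, so the
construction is positive semi-definite by a congruence argument
([[A,γ√A√B],[γ√B√A,B]] = M[[I,γI],[γI,I]]Mᵀ), grid-convergent, and reduces
to independence at γ = 0 and perfect coupling at γ = 1 with equal kernels.
Curves are drawn from the expansion truncated at the top L_true = 20
eigenpairs with scores ξ_r ~ N(0, λ_r) (the top 20 carry 99.98 % of the
trace, so the truncated process's correlation differs from the full one by
< 1e-4).  The population value

    rho_true = ∫ (v₁v₂)^½ C₁₂(t,t) dt / (∫v₁ dt · ∫v₂ dt)^½

is always computed from the constructed operator, never hard-coded; a
dense-grid (J = 1001) evaluation pinned before the estimators were written
(0.48286 scenario 1, 0.47048 scenario 2 at γ = 0.5) serves as a regression
constant in the tests.

What the generator does *not* emulate about real recordings:
non-Gaussian scores, temporal nonstationarity and phase variation,
spatially structured (cross-ROI) noise, and K > 2 dimensions (the API
supports K = 2 only for operator construction; estimation itself is
general-K).  Passing tests therefore certify the estimators under a
smooth, stationary, Gaussian regime, not under every failure mode of real
fMRI data.

## The simulation study and its reference behavior

`run_simulation_study` draws 200 independent replicates per scenario
(deterministic per-replicate substreams from one seed), evaluates each
requested estimator on the (1, 2) pair, and reports bias (mean estimate
minus rho_true), the standard error of the mean estimate, and MSE; the
identity MSE = bias² + population variance holds to rounding and is
asserted in the tests.  A replicate failing for one estimator is dropped
for that estimator only and counted.

Under the defaults, the model-based estimator is nearly unbiased (bias
≈ +0.02 to +0.03 in both scenarios) with MSE ≈ 0.005–0.006, and beats the
naive (MSE ≈ 0.045) and TCC (MSE ≈ 0.21, which estimates a different
functional) by wide margins.  The reconstruction-based univariate
estimator is statistically indistinguishable from the model-based one
under this cross-covariance construction (paired MSE difference
−0.0003 ± 0.0003 over 600 replicates, favoring the model-based estimator
on average): with γ = 0.5 both marginal processes are smooth enough that
per-ROI truncation loses almost nothing, so the multivariate estimator's
advantage — borrowing cross-ROI dependence — is small here by
construction, and a 200-replicate ordering check between the two is a
near-coin-flip.  This is a known limitation of the chosen cross-block
construction, not of the estimator.

## Numerical choices and degenerate inputs

- Variance floor 1e-10; correlation values clipped to [−1, 1] only against
  float overshoot; connectivity matrices symmetrized bitwise.
- Eigenvalues below 1e-12 × λ_max are treated as zero; at least one
  positive eigenvalue is required.
- Strict-inequality truncation rule; positive eigenvalues only in its
  denominator.
- p-values validated to [0, 1]; m̂₀ floored at 1; all-zero p-vectors
  reject everything, all-one p-vectors reject nothing.
- Matrices are exchanged as delimited text at 17 significant digits and
  parsed with round-trip float precision, so write-then-read is exact.
- Subject-matrix files: an optional header row is recognized by the corner
  cell `time`; a non-numeric first column is read as ROI names; ragged or
  non-numeric rows fail with the offending line named.

## Problem sizes in the test suite

The suite exercises the full pipeline at the study's native scale
(200 replicates × n = 100 × J = 51 per scenario) for the headline
simulation checks, and desk-scale instances (K ≤ 3, J ≤ 21, n ≤ 50) for
algebraic oracles; the bootstrap calibration check uses 100 study
replicates of two n = 20 groups at B = 100, chosen to keep the binomial
standard error of the rejection rate near 2 % while the whole suite stays
around a minute.
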