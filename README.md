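# pfcorr

Functional-connectivity analysis for simultaneously recorded signal
profiles — e.g. resting-state fMRI BOLD time courses of cortical regions of
interest (ROIs) — using the **Pearson functional product-moment correlation
(PFCorr)** and multivariate functional principal component analysis
(mFPCA).

Conventional connectivity analysis correlates two time courses point by
point (the "traditional correlation coefficient", TCC), which centers each
series on its own mean: only profile *shapes* matter, relative magnitudes
are discarded, and measurement noise attenuates the estimate.  `pfcorr`
instead treats each ROI's time course as a realization of a random function
X_k(t) on a time domain T and measures association between the random
functions themselves:

    rho_kl = E ∫ (X_k − μ_k)(X_l − μ_l) dt
             ─────────────────────────────────────────────────────
             [E ∫ (X_k − μ_k)² dt]^½ · [E ∫ (X_l − μ_l)² dt]^½

This is the cross-correlation of two random elements of L²(T).  It is
estimated through the multivariate Karhunen–Loève expansion

    X_i(t) = μ(t) + Σ_r ξ_ri (D φ_r)(t),      D(t) = diag(v_k(t)^½),

whose vector eigenfunctions φ_r are shared across ROIs (capturing
within-subject dependence) and whose score variances λ_1 ≥ λ_2 ≥ … are
truncated at the smallest L explaining more than 100·δ % of total variance
(δ = 0.90 by default).  The model-based estimator

    r_kl = Σ_{r≤L} λ̂_r ⟨v̂_k^½ φ̂_kr, v̂_l^½ φ̂_lr⟩ /
           {Σ_{r≤L} λ̂_r ‖v̂_k^½ φ̂_kr‖²}^½ {Σ_{r≤L} λ̂_r ‖v̂_l^½ φ̂_lr‖²}^½

corrects for additive measurement error (per-ROI noise variance σ_k² is
estimated from the covariance diagonal and removed) and lies in [−1, 1] by
Cauchy–Schwarz.

The package provides:

- **`pfcorr.mfpca`** — dense-design mFPCA: moment estimation with
  measurement-error removal, covariance-surface smoothing, the
  quadrature-weighted eigenproblem, subject scores, truncation and
  trajectory reconstruction.
- **`pfcorr.correlation`** — four pairwise estimators (model-based `PFCm`,
  univariate-FPCA `PFCu`, naive plug-in `PFCo`, averaged Pearson `TCC`) and
  K×K connectivity-matrix assembly.
- **`pfcorr.inference`** — pooled-bootstrap two-group test of equal PFCorr
  per ROI pair with an adaptive FDR step-up valid under dependence, plus
  Hotelling T² and bootstrap two-sample mean tests on mFPC scores.
- **`pfcorr.simulate`** — a bivariate Gaussian-process generator
  (Bessel-J₀ / Matérn marginal kernels, tunable cross-correlation γ) and
  the Monte-Carlo estimator-comparison study.
- **`pfcorr.io` / `pfcorr` CLI** — delimited-text readers/writers, study
  manifests, and `estimate` / `test` / `gender-test` / `simulate` / `study`
  subcommands.

## Worked example

```python
import numpy as np
import pfcorr

# a bivariate sample from the scenario-1 Gaussian process:
# n = 100 subjects, 51 time points, noise variances (1, 4), gamma = 0.5
spec = pfcorr.scenario_spec(1, n=100, seed=7)
sample = pfcorr.generate_sample(spec)

dec = pfcorr.fit_mfpca(sample, delta=0.90)
print("retained components L =", dec.L)
print("leading eigenvalues   =", np.round(dec.eigenvalues[:3], 4))
print("sigma^2 estimates     =", np.round(dec.moments.error_variance, 3))
print("PFCm(1,2)             =", round(pfcorr.pfcorr_model(dec, 0, 1), 4))
print("PFCo(1,2)             =", round(pfcorr.pfcorr_naive(sample, 0, 1), 4))
print("population PFCorr     =", round(pfcorr.true_pfcorr(spec), 4))
```

prints

```
retained components L = 3
leading eigenvalues   = [1.2806 0.4968 0.1712]
sigma^2 estimates     = [1.022 4.052]
PFCm(1,2)             = 0.4601
PFCo(1,2)             = 0.2262
population PFCorr     = 0.4828
```

The fit retains 3 components, recovers the generating noise variances
(1 and 4), and the noise-corrected estimate 0.460 sits close to the
population value 0.483, while the naive plug-in estimate 0.226 is badly
attenuated by measurement error.

The same comparison over many replicates, from the command line:

```sh
$ pfcorr study --scenario 1 --replicates 20 --seed 4 --out study.tsv
metric  PFCm       TCC        PFCu       PFCo
bias    0.0229381  -0.462657  -0.0256888 -0.206554
stderr  0.0215032  0.0036251  0.0205004  0.0123527
mse     0.0093115  0.214301   0.00864495 0.0455639
# rho_true=0.4828499577 replicates=20 scenario=1 gamma=0.5 seed=4
```

`bias` is the mean estimate minus the population value, `stderr` the
standard error of the mean estimate, `mse` the mean squared error.  TCC is
far from the functional correlation (it measures a different quantity) and
the naive estimator is attenuated; the FPCA-based estimators are nearly
unbiased.

For real data, point `pfcorr estimate` / `pfcorr test` at a manifest (CSV
with columns `file,subject,group[,sex]`) whose files hold one ROI × time
matrix per subject as delimited text; see `pfcorr --help`.

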