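"""Multivariate functional principal component analysis (mFPCA).

The model for a K-variate random function X_i(t) = (X_1i(t), ..., X_Ki(t))
is the Karhunen-Loeve style expansion

    X_i(t) = mu(t) + sum_r xi_ri (D phi_r)(t),

where D(t) = diag(v_1(t)^{1/2}, ..., v_K(t)^{1/2}) carries the pointwise
variance functions, the vector eigenfunctions phi_r = (phi_1r, ..., phi_Kr)
are jointly orthonormal (sum_k <phi_kr, phi_kr'> = delta_rr'), and the
scores xi_ri are uncorrelated with variances lambda_1 >= lambda_2 >= ...

Observations Y_ij = X_i(t_j) + eps_ij are contaminated by i.i.d. noise with
per-ROI variance sigma_k^2.  Estimation on a dense common grid proceeds by

1. cross-sectional moments; the noise-free variance function v_k(t) is the
   covariance diagonal re-estimated from off-diagonal entries by a
   local-linear surface fit, and sigma_k^2 is the average gap between the
   raw and the smoothed diagonal;
2. the sample covariance of the normalized residuals
   Z_ki(t) = v_k(t)^{-1/2} (Y_ki(t) - mu_k(t)), with the noise contribution
   sigma_k^2 / v_k(t_j) removed from the diagonal of each auto-block;
3. eigendecomposition of the quadrature-weighted stacked operator, and
   scores by quadrature inner products of Z against the eigenfunctions.
"""

from __future__ import annotations

import numpy as np

from .fdcore import (
    MFPCDecomposition,
    MomentEstimates,
    MultivariateFunctionalSample,
    SmoothConfig,
    ValidationError,
    local_linear_smoother_matrix,
    smooth_covariance_diagonal,
)

__all__ = ["estimate_moments", "fit_mfpca", "select_num_components", "reconstruct"]


def estimate_moments(
    sample: MultivariateFunctionalSample, smooth: SmoothConfig | None = None
) -> MomentEstimates:
    """Estimate mean, variance function and measurement-error variance.

    The raw pointwise variance (unbiased, n-1 denominator) contains the
    error variance sigma_k^2 on top of v_k(t); with ``correct_noise`` the
    variance function is recovered from the off-diagonal of the
    auto-covariance surface and sigma_k^2 from the diagonal gap, averaged
    over the grid and clipped at zero.
    """
    smooth = smooth or SmoothConfig()
    Y = sample.values
    n, K, J = Y.shape
    if n < 2:
        raise ValidationError("moment estimation requires n >= 2")
    grid = sample.grid

    mean = Y.mean(axis=0)
    if smooth.smooth_mean:
        h = smooth.mean_bandwidth * grid.span
        S = local_linear_smoother_matrix(grid.points, grid.points, h)
        mean = mean @ S.T

    resid = Y - mean[None, :, :]
    raw_var = (resid**2).sum(axis=0) / (n - 1)

    variance = np.empty_like(raw_var)
    sigma2 = np.zeros(K)
    if smooth.correct_noise:
        h = smooth.diag_bandwidth * grid.span
        for k in range(K):
            cov_k = resid[:, k, :].T @ resid[:, k, :] / (n - 1)
            smoothed = smooth_covariance_diagonal(grid, cov_k, h)
            variance[k] = smoothed
            sigma2[k] = max(0.0, float(np.mean(raw_var[k] - smoothed)))
    else:
        variance[:] = raw_var

    variance = np.maximum(variance, smooth.variance_floor)
    return MomentEstimates(
        mean=mean,
        variance=variance,
        error_variance=sigma2,
        raw_variance=raw_var,
        smoothing_meta={
            "smooth_mean": smooth.smooth_mean,
            "correct_noise": smooth.correct_noise,
            "diag_bandwidth": smooth.diag_bandwidth,
            "variance_floor": smooth.variance_floor,
        },
    )


def select_num_components(eigenvalues: np.ndarray, delta: float) -> int:
    """Smallest L whose leading eigenvalues explain more than 100*delta
    percent of the total variance.

    Only strictly positive eigenvalues enter the denominator; the
    inequality is strict, so e.g. eigenvalues (6, 3, 1) at delta = 0.9
    give L = 3 (cumulative fraction 0.9 does not exceed 0.9).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if not 0.0 < delta < 1.0:
        raise ValidationError("delta must lie in (0, 1)")
    if lam.size == 0 or np.any(np.diff(lam) > 1e-12 * max(1.0, abs(lam[0]))):
        raise ValidationError("eigenvalues must be non-ascending")
    total = lam[lam > 0].sum()
    if total <= 0:
        raise ValidationError("need at least one positive eigenvalue")
    frac = np.cumsum(lam) / total
    passing = np.nonzero(frac > delta)[0]
    if passing.size == 0:  # numerically frac[-1] == 1 always passes delta < 1
        return int(lam.size)
    return int(passing[0]) + 1


def fit_mfpca(
    sample: MultivariateFunctionalSample,
    delta: float = 0.90,
    smooth: SmoothConfig | None = None,
    max_components: int | None = None,
) -> MFPCDecomposition:
    """Fit the mFPCA model to a dense multivariate functional sample.

    Parameters
    ----------
    sample
        Observations, shape (n, K, J) on a shared grid.
    delta
        Fraction of variance the retained components must exceed
        (default 0.90).
    smooth
        Moment-smoothing configuration; see :class:`SmoothConfig`.
    max_components
        Optional cap on the number of stored eigenpairs (all positive ones
        by default).
    """
    if not 0.0 < delta < 1.0:
        raise ValidationError("delta must lie in (0, 1)")
    smooth = smooth or SmoothConfig()
    moments = estimate_moments(sample, smooth)
    grid = sample.grid
    Y = sample.values
    n, K, J = Y.shape

    # normalized residuals Z, stacked over ROIs: (n, K*J)
    Z = (Y - moments.mean[None]) / np.sqrt(moments.variance)[None]
    Zs = Z.reshape(n, K * J)
    C = Zs.T @ Zs / (n - 1)

    if smooth.correct_noise:
        # remove the noise ridge sigma_k^2 / v_k(t_j) from auto-block diagonals
        noise_diag = (moments.error_variance[:, None] / moments.variance).ravel()
        C[np.diag_indices_from(C)] -= noise_diag

    if smooth.smooth_surface:
        # tensor-product local-linear smoothing, (I_K kron S) C (I_K kron S)^T;
        # suppresses the rough sampling-noise directions of the raw covariance
        S = local_linear_smoother_matrix(
            grid.points, grid.points, smooth.surface_bandwidth * grid.span
        )
        C4 = C.reshape(K, J, K, J)
        C = np.einsum("pa,kalb,qb->kplq", S, C4, S).reshape(K * J, K * J)

    w = np.tile(grid.weights, K)
    sw = np.sqrt(w)
    A = sw[:, None] * C * sw[None, :]
    A = (A + A.T) / 2.0
    lam, U = np.linalg.eigh(A)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    U = U[:, order]

    tol = max(abs(lam[0]), 1.0) * 1e-12
    lam = np.where(lam > tol, lam, 0.0)
    n_pos = int(np.count_nonzero(lam))
    if n_pos < 1:
        raise ValidationError("covariance operator has no positive eigenvalues")
    R = n_pos if max_components is None else min(n_pos, max_components)

    phi = (U[:, :R] / sw[:, None]).T.reshape(R, K, J)
    # renormalize under quadrature (exact up to rounding) and fix signs
    norms = np.sqrt(np.einsum("rkj,rkj,j->r", phi, phi, grid.weights))
    phi /= norms[:, None, None]
    flat = phi.reshape(R, K * J)
    idx = np.argmax(np.abs(flat), axis=1)
    signs = np.sign(flat[np.arange(R), idx])
    signs[signs == 0] = 1.0
    phi *= signs[:, None, None]

    # scores by quadrature inner products of Z against phi
    scores = np.einsum("ikj,rkj,j->ir", Z, phi, grid.weights)

    L = select_num_components(lam[:n_pos], delta)
    L = min(L, R)
    return MFPCDecomposition(
        grid=grid,
        moments=moments,
        eigenvalues=lam[:R],
        eigenfunctions=phi,
        scores=scores,
        L=L,
        delta=delta,
        roi_names=list(sample.roi_names),
        group_label=sample.group_label,
    )


def reconstruct(decomp: MFPCDecomposition, L: int | None = None) -> np.ndarray:
    """Predicted trajectories ``mu + sum_{r<=L} xi_r (D phi_r)``, shape (n, K, J)."""
    if L is None:
        L = decomp.L
    if not 1 <= L <= decomp.n_components:
        raise ValidationError(f"L must be in [1, {decomp.n_components}]")
    D = np.sqrt(decomp.moments.variance)  # (K, J)
    basis = decomp.eigenfunctions[:L] * D[None]  # (L, K, J)
    fitted = np.einsum("ir,rkj->ikj", decomp.scores[:, :L], basis)
    return decomp.moments.mean[None] + fitted
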