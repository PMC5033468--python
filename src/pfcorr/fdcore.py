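"""Core functional-data containers, quadrature and smoothing utilities.

Observed data are dense multivariate functional samples: for each subject
``i`` and region of interest (ROI) ``k`` a time course is recorded on a
grid shared by every subject.  All integrals in the package reduce to
quadrature sums ``sum_j w_j f(t_j)`` against the grid's trapezoid weights,
which keeps every inner product symmetric and makes the discretized
covariance eigenproblem a standard symmetric one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "DegenerateCorrelationError",
    "TimeGrid",
    "MultivariateFunctionalSample",
    "MomentEstimates",
    "MFPCDecomposition",
    "SmoothConfig",
    "make_trapezoid_grid",
    "integrate",
    "resample_to_grid",
    "local_linear_smoother_matrix",
    "smooth_covariance_diagonal",
]

#: lower bound applied to variance functions before forming v^{-1/2}
VARIANCE_FLOOR = 1e-10


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class DegenerateCorrelationError(ValueError):
    """Raised when a correlation is undefined (zero variation)."""


@dataclass(frozen=True)
class TimeGrid:
    """Shared sampling grid with quadrature weights.

    Parameters
    ----------
    points
        Strictly increasing time samples ``t_1 < ... < t_J``, ``J >= 2``.
    weights
        Positive quadrature weights summing to ``t_J - t_1`` (trapezoid
        convention).
    """

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        wts = np.asarray(self.weights, dtype=float)
        if pts.ndim != 1 or pts.size < 2:
            raise ValidationError("grid needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("grid points must be finite")
        if np.any(np.diff(pts) <= 0):
            raise ValidationError("grid points must be strictly increasing")
        if wts.shape != pts.shape:
            raise ValidationError("weights must match points in length")
        if np.any(wts <= 0):
            raise ValidationError("quadrature weights must be positive")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", wts)

    @property
    def n_points(self) -> int:
        return self.points.size

    @property
    def span(self) -> float:
        return float(self.points[-1] - self.points[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeGrid):
            return NotImplemented
        return np.array_equal(self.points, other.points) and np.array_equal(
            self.weights, other.weights
        )


def make_trapezoid_grid(points: Sequence[float]) -> TimeGrid:
    """Build a :class:`TimeGrid` with composite-trapezoid weights.

    The weight of an interior point is half the span of its two adjacent
    intervals; endpoints get half their single interval.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 1 or pts.size < 2:
        raise ValidationError("need at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("points must be finite")
    if np.any(np.diff(pts) <= 0):
        raise ValidationError("points must be strictly increasing")
    w = np.zeros_like(pts)
    dt = np.diff(pts)
    w[:-1] += dt / 2.0
    w[1:] += dt / 2.0
    return TimeGrid(points=pts, weights=w)


def integrate(grid: TimeGrid, f: np.ndarray) -> float:
    """Quadrature integral ``sum_j w_j f(t_j)`` over the grid's domain."""
    f = np.asarray(f, dtype=float)
    if f.shape[-1] != grid.n_points:
        raise ValidationError(
            f"function values have length {f.shape[-1]}, grid has {grid.n_points}"
        )
    return f @ grid.weights


@dataclass
class MultivariateFunctionalSample:
    """One group's observations: ``n`` subjects x ``K`` ROIs x ``J`` times.

    ``values[i, k, j]`` holds the observed (noise-contaminated) signal of
    subject ``i`` in ROI ``k`` at grid point ``t_j``.
    """

    grid: TimeGrid
    values: np.ndarray
    group_label: str = ""
    subject_ids: list[str] = field(default_factory=list)
    roi_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("values must be (subject, ROI, time)")
        n, K, J = self.values.shape
        if J != self.grid.n_points:
            raise ValidationError("time axis does not match the grid")
        if n < 2:
            raise ValidationError("need at least 2 subjects")
        if K < 1:
            raise ValidationError("need at least 1 ROI")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("all observations must be finite")
        if not self.subject_ids:
            self.subject_ids = [f"s{i}" for i in range(n)]
        if not self.roi_names:
            self.roi_names = [f"roi{k}" for k in range(K)]
        if len(self.subject_ids) != n:
            raise ValidationError("subject_ids length mismatch")
        if len(self.roi_names) != K:
            raise ValidationError("roi_names length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class SmoothConfig:
    """Smoothing configuration for moment estimation.

    Attributes
    ----------
    smooth_mean
        Local-linear smooth of the cross-sectional mean (off by default;
        dense designs average out noise already).
    mean_bandwidth, diag_bandwidth, variance_bandwidth
        Gaussian-kernel bandwidths as a fraction of the grid span.  The
        diagonal bandwidth controls the off-diagonal local-linear fit used
        to remove measurement-error variance from the covariance diagonal.
    correct_noise
        When False the raw pointwise variance is used as the variance
        function and no error variance is removed (useful for noiseless
        data and for oracle comparisons).
    smooth_surface, surface_bandwidth
        Tensor-product local-linear smoothing of the full covariance
        surface before the eigendecomposition.  On dense noisy designs the
        raw sample covariance carries a floor of rough sampling-noise
        eigenvectors that inflates the tail of the spectrum, drags the
        variance-explained truncation rule to large L and attenuates the
        model-based correlation; surface smoothing suppresses exactly
        those rough directions, so it is on by default.
    """

    smooth_mean: bool = False
    mean_bandwidth: float = 0.1
    diag_bandwidth: float = 0.1
    variance_bandwidth: float = 0.1
    correct_noise: bool = True
    smooth_surface: bool = True
    surface_bandwidth: float = 0.1
    variance_floor: float = VARIANCE_FLOOR


@dataclass
class MomentEstimates:
    """First and second pointwise moments of one group.

    ``variance`` is the (noise-free) variance function v_k(t); the raw
    pointwise sample variance of the observations, which still contains the
    measurement-error variance, is kept in ``raw_variance``.
    """

    mean: np.ndarray            # (K, J)
    variance: np.ndarray        # (K, J), floored at variance_floor
    error_variance: np.ndarray  # (K,), sigma_k^2 >= 0
    raw_variance: np.ndarray    # (K, J)
    smoothing_meta: dict = field(default_factory=dict)


@dataclass
class MFPCDecomposition:
    """Fitted multivariate functional principal component model.

    Eigenfunctions are stored as ``eigenfunctions[r, k, j]`` and satisfy the
    joint orthonormality ``sum_k <phi_kr, phi_kr'> = delta_rr'`` under the
    grid quadrature.  ``scores[i, r]`` are subject scores of the centered,
    variance-normalized data.
    """

    grid: TimeGrid
    moments: MomentEstimates
    eigenvalues: np.ndarray      # (R,), non-ascending, >= 0
    eigenfunctions: np.ndarray   # (R, K, J)
    scores: np.ndarray           # (n, R)
    L: int
    delta: float
    roi_names: list[str] = field(default_factory=list)
    group_label: str = ""

    @property
    def n_components(self) -> int:
        return int(self.eigenvalues.size)


def resample_to_grid(
    sample: MultivariateFunctionalSample, target: TimeGrid
) -> MultivariateFunctionalSample:
    """Linearly interpolate every subject's curves onto ``target``.

    Explicit utility for harmonizing grids; grid mismatch elsewhere in the
    package is an error rather than a silent interpolation.
    """
    lo, hi = sample.grid.points[0], sample.grid.points[-1]
    if target.points[0] < lo or target.points[-1] > hi:
        raise ValidationError("target grid extends beyond the observed domain")
    n, K, _ = sample.values.shape
    out = np.empty((n, K, target.n_points))
    for i in range(n):
        for k in range(K):
            out[i, k] = np.interp(target.points, sample.grid.points, sample.values[i, k])
    return MultivariateFunctionalSample(
        grid=target,
        values=out,
        group_label=sample.group_label,
        subject_ids=list(sample.subject_ids),
        roi_names=list(sample.roi_names),
    )


def local_linear_smoother_matrix(
    x_in: np.ndarray, x_out: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Hat matrix ``S`` of a Gaussian-kernel local-linear smoother.

    ``S @ y`` evaluates the local-linear fit of ``(x_in, y)`` at ``x_out``.
    Smoothing is linear in the data, so precomputing ``S`` turns repeated
    smooths (e.g. inside a bootstrap) into matrix-vector products.
    """
    x_in = np.asarray(x_in, dtype=float)
    x_out = np.asarray(x_out, dtype=float)
    if bandwidth <= 0:
        raise ValidationError("bandwidth must be positive")
    d = x_in[None, :] - x_out[:, None]          # (J_out, J_in)
    w = np.exp(-0.5 * (d / bandwidth) ** 2)
    s0 = w.sum(axis=1, keepdims=True)
    s1 = (w * d).sum(axis=1, keepdims=True)
    s2 = (w * d * d).sum(axis=1, keepdims=True)
    denom = s0 * s2 - s1 * s1
    # fall back to a kernel average where the local design is singular
    small = denom <= 1e-300
    L = np.where(small, w / np.maximum(s0, 1e-300), w * (s2 - d * s1) / np.where(small, 1.0, denom))
    return L


def smooth_covariance_diagonal(
    grid: TimeGrid, cov: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Estimate ``C(t_j, t_j)`` by a local-linear surface fit off the diagonal.

    The raw sample covariance of noisy observations is inflated by the
    measurement-error variance exactly on the diagonal; fitting the smooth
    surface from off-diagonal entries and evaluating it at ``(t, t)``
    recovers the noise-free variance function.
    """
    t = grid.points
    J = t.size
    if cov.shape != (J, J):
        raise ValidationError("covariance must be J x J")
    h = bandwidth
    S, T = np.meshgrid(t, t, indexing="ij")
    off = ~np.eye(J, dtype=bool)
    s = S[off]
    u = T[off]
    c = cov[off]
    out = np.empty(J)
    for j in range(J):
        ds = s - t[j]
        du = u - t[j]
        w = np.exp(-0.5 * ((ds / h) ** 2 + (du / h) ** 2))
        X = np.column_stack([np.ones_like(ds), ds, du])
        Xw = X * w[:, None]
        A = Xw.T @ X
        b = Xw.T @ c
        try:
            beta = np.linalg.solve(A, b)
            out[j] = beta[0]
        except np.linalg.LinAlgError:
            out[j] = np.average(c, weights=w)
    return out
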