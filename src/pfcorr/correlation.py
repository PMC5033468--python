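"""Pairwise functional-connectivity estimators and CCC matrix assembly.

The Pearson functional correlation (PFCorr) between two random functions
X_k and X_l over a time domain T is

    rho_kl = E int (X_k - mu_k)(X_l - mu_l) dt
             / [ E int (X_k - mu_k)^2 dt ]^{1/2} [ E int (X_l - mu_l)^2 dt ]^{1/2},

i.e. the cross-correlation of two random elements of L^2(T).  Four
estimators are provided:

``PFCm``
    model-based, via the fitted mFPCA decomposition (noise-corrected,
    shares components across ROIs);
``PFCu``
    same quantity from per-ROI univariate FPCA reconstructions (noise-
    corrected but ignores cross-ROI dependence);
``PFCo``
    naive plug-in on the raw observations (no noise correction);
``TCC``
    per-subject Pearson correlation of the two time courses, averaged over
    subjects.  Each series is centered on its own mean, so only profile
    shapes matter, not relative magnitudes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .fdcore import (
    DegenerateCorrelationError,
    MFPCDecomposition,
    MultivariateFunctionalSample,
    SmoothConfig,
    TimeGrid,
    ValidationError,
)
from .mfpca import fit_mfpca

__all__ = [
    "ConnectivityMatrix",
    "tcc_pair",
    "tcc_matrix",
    "pfcorr_model",
    "pfcorr_model_matrix",
    "pfcorr_naive",
    "pfcorr_univariate",
    "connectivity_matrix",
    "ESTIMATOR_TAGS",
]

logger = logging.getLogger(__name__)

ESTIMATOR_TAGS = ("PFCm", "PFCu", "PFCo", "TCC")


@dataclass
class ConnectivityMatrix:
    """K x K symmetric matrix of pairwise functional correlations.

    Degenerate pairs (no retained variation) are stored as NaN rather than
    aborting the whole matrix.
    """

    values: np.ndarray
    estimator_tag: str
    roi_names: list[str] = field(default_factory=list)
    group_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError("connectivity matrix must be square")
        if self.estimator_tag not in ESTIMATOR_TAGS:
            raise ValidationError(f"unknown estimator tag {self.estimator_tag!r}")
        if not self.roi_names:
            self.roi_names = [f"roi{k}" for k in range(self.values.shape[0])]

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_pairs(self) -> int:
        K = self.n_rois
        return K * (K - 1) // 2


def _clip_corr(x: float) -> float:
    # Cauchy-Schwarz guarantees |rho| <= 1; trim float overshoot only
    return float(min(1.0, max(-1.0, x)))


def tcc_pair(f: np.ndarray, r: np.ndarray) -> float:
    """Pearson correlation of two equally long time courses."""
    f = np.asarray(f, dtype=float)
    r = np.asarray(r, dtype=float)
    if f.shape != r.shape or f.ndim != 1 or f.size < 2:
        raise ValidationError("series must be 1-D, equal length >= 2")
    fc = f - f.mean()
    rc = r - r.mean()
    den = np.sqrt((fc @ fc) * (rc @ rc))
    if den == 0:
        raise DegenerateCorrelationError("constant series has undefined correlation")
    return _clip_corr((fc @ rc) / den)


def tcc_matrix(sample: MultivariateFunctionalSample) -> ConnectivityMatrix:
    """Average over subjects of the per-subject pairwise Pearson correlations.

    Subjects with a constant series in one ROI are excluded from every pair
    involving that ROI (with a logged warning).
    """
    Y = sample.values
    n, K, _ = Y.shape
    centered = Y - Y.mean(axis=2, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=2))  # (n, K)
    ok = norms > 0
    if not ok.all():
        bad = int((~ok).sum())
        logger.warning("tcc_matrix: %d constant subject/ROI series excluded", bad)
    acc = np.zeros((K, K))
    cnt = np.zeros((K, K))
    for i in range(n):
        u = centered[i][ok[i]]
        nrm = norms[i][ok[i]]
        corr = (u @ u.T) / np.outer(nrm, nrm)
        mask = np.ix_(ok[i], ok[i])
        acc[mask] += corr
        cnt[mask] += 1
    with np.errstate(invalid="ignore"):
        vals = acc / cnt
    np.fill_diagonal(vals, 1.0)
    vals = np.clip(vals, -1.0, 1.0)
    return ConnectivityMatrix(
        values=vals,
        estimator_tag="TCC",
        roi_names=list(sample.roi_names),
        group_label=sample.group_label,
    )


def _model_gram(decomp: MFPCDecomposition, L: int | None = None) -> np.ndarray:
    """K x K matrix N_kl = sum_{r<=L} lambda_r <v_k^{1/2} phi_kr, v_l^{1/2} phi_lr>."""
    if L is None:
        L = decomp.L
    if not 1 <= L <= decomp.n_components:
        raise ValidationError(f"L must be in [1, {decomp.n_components}]")
    psi = decomp.eigenfunctions[:L] * np.sqrt(decomp.moments.variance)[None]  # (L,K,J)
    lam = decomp.eigenvalues[:L]
    return np.einsum("r,rkj,rlj,j->kl", lam, psi, psi, decomp.grid.weights)


def pfcorr_model(decomp: MFPCDecomposition, k: int, l: int, L: int | None = None) -> float:
    """Model-based sample PFCorr of the ROI pair (k, l).

    r_kl = sum_r lambda_r <v_k^{1/2} phi_kr, v_l^{1/2} phi_lr>
           / { sum_r lambda_r ||v_k^{1/2} phi_kr||^2 }^{1/2}
             { sum_r lambda_r ||v_l^{1/2} phi_lr||^2 }^{1/2},

    summing over the retained components r <= L; inner products and norms
    are quadrature integrals over the time domain.
    """
    N = _model_gram(decomp, L)
    if N[k, k] <= 0 or N[l, l] <= 0:
        raise DegenerateCorrelationError("ROI with no retained variation")
    return _clip_corr(N[k, l] / np.sqrt(N[k, k] * N[l, l]))


def pfcorr_model_matrix(decomp: MFPCDecomposition, L: int | None = None) -> np.ndarray:
    """All pairwise model-based PFCorr values at once (NaN for degenerate ROIs)."""
    N = _model_gram(decomp, L)
    d = np.diag(N).copy()
    bad = d <= 0
    d[bad] = np.nan
    with np.errstate(invalid="ignore"):
        vals = N / np.sqrt(np.outer(d, d))
    vals = np.clip((vals + vals.T) / 2.0, -1.0, 1.0)  # bitwise symmetry
    np.fill_diagonal(vals, np.where(bad, np.nan, 1.0))
    return vals


def _plugin_gram(values: np.ndarray, mean: np.ndarray, grid: TimeGrid) -> np.ndarray:
    """K x K plug-in Gram: mean over subjects of int (Y_k - mu_k)(Y_l - mu_l) dt."""
    resid = values - mean[None]
    return np.einsum("ikj,ilj,j->kl", resid, resid, grid.weights) / values.shape[0]


def pfcorr_naive(
    sample: MultivariateFunctionalSample, k: int, l: int
) -> float:
    """Naive plug-in PFCorr: observations stand in for the latent functions.

    The population expectations become cross-sectional means and the
    integrals quadrature sums; measurement error is not corrected, which
    attenuates the estimate when the noise variance is non-negligible.
    """
    N = _plugin_gram(sample.values, sample.values.mean(axis=0), sample.grid)
    if N[k, k] <= 0 or N[l, l] <= 0:
        raise DegenerateCorrelationError("ROI without variation")
    return _clip_corr(N[k, l] / np.sqrt(N[k, k] * N[l, l]))


def _plugin_matrix(values: np.ndarray, grid: TimeGrid) -> np.ndarray:
    N = _plugin_gram(values, values.mean(axis=0), grid)
    d = np.diag(N).copy()
    bad = d <= 0
    d[bad] = np.nan
    with np.errstate(invalid="ignore"):
        vals = N / np.sqrt(np.outer(d, d))
    vals = np.clip((vals + vals.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(vals, np.where(bad, np.nan, 1.0))
    return vals


def pfcorr_univariate(
    sample: MultivariateFunctionalSample,
    k: int,
    l: int,
    delta: float = 0.90,
    smooth: SmoothConfig | None = None,
) -> float:
    """PFCorr from per-ROI univariate FPCA reconstructions.

    Each ROI is decomposed on its own (K = 1 instance of the mFPCA
    machinery, noise-corrected, truncation chosen per ROI by the same
    variance-explained rule), and the plug-in PFCorr is evaluated on the
    two reconstructed trajectories.  Unlike the model-based estimator this
    shares no components across ROIs.
    """
    vals = _univariate_reconstructions(sample, delta, smooth, rois=(k, l))
    N = _plugin_gram(vals, vals.mean(axis=0), sample.grid)
    if N[0, 0] <= 0 or N[1, 1] <= 0:
        raise DegenerateCorrelationError("ROI without retained variation")
    return _clip_corr(N[0, 1] / np.sqrt(N[0, 0] * N[1, 1]))


def _univariate_reconstructions(
    sample: MultivariateFunctionalSample,
    delta: float,
    smooth: SmoothConfig | None,
    rois: tuple[int, ...] | None = None,
) -> np.ndarray:
    from .mfpca import reconstruct  # local import to avoid cycle at module load

    rois = tuple(range(sample.n_rois)) if rois is None else rois
    out = np.empty((sample.n_subjects, len(rois), sample.grid.n_points))
    for pos, k in enumerate(rois):
        sub = MultivariateFunctionalSample(
            grid=sample.grid,
            values=sample.values[:, [k], :],
            group_label=sample.group_label,
            subject_ids=list(sample.subject_ids),
            roi_names=[sample.roi_names[k]],
        )
        dec = fit_mfpca(sub, delta=delta, smooth=smooth)
        out[:, pos, :] = reconstruct(dec, dec.L)[:, 0, :]
    return out


def connectivity_matrix(
    obj: MFPCDecomposition | MultivariateFunctionalSample,
    estimator_tag: str,
    delta: float = 0.90,
    smooth: SmoothConfig | None = None,
) -> ConnectivityMatrix:
    """Assemble the full K x K connectivity (CCC) matrix under one estimator.

    ``PFCm`` requires a fitted :class:`MFPCDecomposition`; the other
    estimators work from the raw sample.  All K(K-1)/2 unordered pairs are
    filled, the diagonal is 1, and the matrix is symmetric by construction.
    """
    if estimator_tag not in ESTIMATOR_TAGS:
        raise ValidationError(
            f"unknown estimator {estimator_tag!r}; expected one of {ESTIMATOR_TAGS}"
        )
    if estimator_tag == "PFCm":
        if isinstance(obj, MultivariateFunctionalSample):
            obj = fit_mfpca(obj, delta=delta, smooth=smooth)
        vals = pfcorr_model_matrix(obj)
        return ConnectivityMatrix(
            values=vals,
            estimator_tag="PFCm",
            roi_names=list(obj.roi_names),
            group_label=obj.group_label,
        )
    if not isinstance(obj, MultivariateFunctionalSample):
        raise ValidationError(f"estimator {estimator_tag} requires a raw sample")
    if estimator_tag == "TCC":
        return tcc_matrix(obj)
    if estimator_tag == "PFCo":
        vals = _plugin_matrix(obj.values, obj.grid)
    else:  # PFCu
        recon = _univariate_reconstructions(obj, delta, smooth)
        vals = _plugin_matrix(recon, obj.grid)
    if np.isnan(vals).any():
        warnings.warn("degenerate ROI pair(s) flagged as NaN", stacklevel=2)
    return ConnectivityMatrix(
        values=vals,
        estimator_tag=estimator_tag,
        roi_names=list(obj.roi_names),
        group_label=obj.group_label,
    )
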