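"""Two-group inference on functional connectivity.

The group-difference test asks, for every ROI pair (k, l), whether the
model-based functional correlation differs between two groups (e.g. young
vs elderly).  The null distribution of the paired difference is obtained by
a pooled bootstrap: both groups' resamples are drawn, with replacement,
from the subjects of the *combined* sample, which imposes the null of equal
correlation while preserving the within-subject dependence structure.  The
resulting per-pair p-values are corrected by an adaptive step-up rule valid
under dependence (a Benjamini-Hochberg variant with a harmonic-sum penalty
and an estimated number of true nulls).

Bootstrap procedure (B replicates, pooled n = n1 + n2):

1. pool the two groups' observations;
2. fit the pooled mFPCA, retaining M components by the variance-explained
   rule, and keep the pooled mean, variance and eigenfunctions fixed;
3. resample subject indices with replacement n times;
4. the first n1 resampled subjects form the group-1 replicate, the rest
   group 2; per group, re-estimate the eigenvalues as sample variances of
   the resampled scores, and the variance function by local-linear
   smoothing of the mean squared residuals;
5. recompute the model-based correlation of every pair per group;
6. p-value of pair (k, l): fraction of replicates whose |difference|
   exceeds the observed |difference|;
7. adaptive FDR step-up on the K(K-1)/2 p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fdcore import (
    MultivariateFunctionalSample,
    SmoothConfig,
    ValidationError,
    local_linear_smoother_matrix,
)
from .mfpca import fit_mfpca
from .correlation import pfcorr_model_matrix

__all__ = [
    "GroupDifferenceResult",
    "bootstrap_group_difference",
    "fdr_adaptive_stepup",
    "adjusted_pvalues",
    "hotelling_two_sample",
    "bootstrap_mean_test",
]


@dataclass
class GroupDifferenceResult:
    """Outcome of the bootstrap two-group connectivity-difference test."""

    U: np.ndarray                 # (K, K) observed differences r2 - r1
    pvalues: np.ndarray           # (K, K) unadjusted bootstrap p-values
    rejected: set = field(default_factory=set)  # unordered (k, l) pairs, k < l
    m0_hat: int = 0
    Q: int = 0
    alpha: float = 0.05
    B: int = 0
    seed: int | None = None
    roi_names: list[str] = field(default_factory=list)
    adjusted: np.ndarray | None = None


def _pair_indices(K: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(K, k=1)


def fdr_adaptive_stepup(
    pvalues: np.ndarray,
    alpha: float,
    force_m0: int | None = None,
    harmonic: bool = True,
) -> tuple[list[int], int, int]:
    """Adaptive step-up FDR rule valid under dependence.

    Sorting the m p-values ascending, define

        q(m0) = max{ q : P_(q) <= (q / m0) * alpha / H },

    with H = sum_{j=1}^m 1/j (the dependence penalty; ``harmonic=False``
    drops it), and estimate the number of true nulls as
    m0_hat = max{ L >= 1 : L <= m - q(L) }, floored at 1 when no L
    qualifies.  The Q = q(m0_hat) smallest p-values are rejected (stable
    original order breaks ties).  With ``force_m0 = m`` and
    ``harmonic=False`` this is the classic Benjamini-Hochberg step-up.

    Returns (rejected original indices, m0_hat, Q).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValidationError("need a 1-D vector of p-values")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    H = np.sum(1.0 / np.arange(1, m + 1)) if harmonic else 1.0
    q_grid = np.arange(1, m + 1)

    def q_of(m0: int) -> int:
        thresh = (q_grid / m0) * alpha / H
        passing = np.nonzero(ps <= thresh)[0]
        return 0 if passing.size == 0 else int(passing[-1]) + 1

    if force_m0 is not None:
        m0_hat = int(force_m0)
    else:
        qualifying = [L for L in range(1, m + 1) if L <= m - q_of(L)]
        m0_hat = max(qualifying) if qualifying else 1
    Q = q_of(m0_hat)
    rejected = [int(i) for i in order[:Q]]
    return rejected, m0_hat, Q


def adjusted_pvalues(pvalues: np.ndarray, harmonic: bool = True) -> np.ndarray:
    """Step-up-consistent adjusted p-values (Benjamini-Yekutieli style).

    adj_(q) = min_{q' >= q} min(1, m * H * P_(q') / q'); a hypothesis is
    rejected at level alpha by the non-adaptive (m0 = m) step-up exactly
    when its adjusted value is <= alpha.  These are a reporting convenience
    derived from the rejection rule, not an ingredient of it.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    H = np.sum(1.0 / np.arange(1, m + 1)) if harmonic else 1.0
    raw = m * H * ps / np.arange(1, m + 1)
    adj = np.minimum.accumulate(raw[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _group_pfcorr_from_pooled(
    pooled_phi: np.ndarray,
    weights: np.ndarray,
    scores: np.ndarray,
    values: np.ndarray,
    mean: np.ndarray,
    smoother: np.ndarray,
    variance_floor: float,
) -> np.ndarray:
    """Model-based correlation matrix of one bootstrap group replicate.

    Eigenvalues are the sample variances of the group's resampled pooled
    scores; the variance function is a local-linear smooth of the group's
    mean squared residuals about its own mean.
    """
    n = values.shape[0]
    lam = scores.var(axis=0, ddof=1)  # (M,)
    resid2 = ((values - mean[None]) ** 2).mean(axis=0)  # (K, J)
    v = np.maximum(resid2 @ smoother.T, variance_floor)  # (K, J)
    psi = pooled_phi * np.sqrt(v)[None]  # (M, K, J)
    N = np.einsum("r,rkj,rlj,j->kl", lam, psi, psi, weights)
    d = np.diag(N).copy()
    d[d <= 0] = np.nan
    with np.errstate(invalid="ignore"):
        vals = np.clip(N / np.sqrt(np.outer(d, d)), -1.0, 1.0)
    return vals


def bootstrap_group_difference(
    sample1: MultivariateFunctionalSample,
    sample2: MultivariateFunctionalSample,
    B: int = 1000,
    delta: float = 0.90,
    alpha: float = 0.05,
    seed: int | None = None,
    smooth: SmoothConfig | None = None,
    variance_bandwidth: float = 0.1,
) -> GroupDifferenceResult:
    """Pooled-bootstrap test of equal PFCorr between two groups.

    The observed difference matrix ``U = r2 - r1`` comes from separate
    per-group mFPCA fits; the bootstrap null distribution follows the
    pooled procedure described in the module docstring.  Deterministic
    given ``seed``.
    """
    if sample1.grid != sample2.grid:
        raise ValidationError("groups must share the sampling grid")
    if sample1.roi_names != sample2.roi_names:
        raise ValidationError("groups must share the ROI set and order")
    if B < 1:
        raise ValidationError("B must be >= 1")
    smooth = smooth or SmoothConfig()
    n1, K, J = sample1.values.shape
    n2 = sample2.values.shape[0]
    n = n1 + n2
    grid = sample1.grid

    # observed differences from group-specific fits
    dec1 = fit_mfpca(sample1, delta=delta, smooth=smooth)
    dec2 = fit_mfpca(sample2, delta=delta, smooth=smooth)
    U = pfcorr_model_matrix(dec2) - pfcorr_model_matrix(dec1)

    # pooled fit: mean, variance, eigenfunctions and scores held fixed
    pooled = MultivariateFunctionalSample(
        grid=grid,
        values=np.concatenate([sample1.values, sample2.values], axis=0),
        group_label="pooled",
        subject_ids=list(sample1.subject_ids) + list(sample2.subject_ids),
        roi_names=list(sample1.roi_names),
    )
    pdec = fit_mfpca(pooled, delta=delta, smooth=smooth)
    M = pdec.L
    phi = pdec.eigenfunctions[:M]
    scores = pdec.scores[:, :M]
    smoother = local_linear_smoother_matrix(
        grid.points, grid.points, variance_bandwidth * grid.span
    )

    ik, il = _pair_indices(K)
    exceed = np.zeros(len(ik))
    obs = np.abs(U[ik, il])
    for b in range(B):
        # deterministic substream per replicate for reproducibility
        sub = np.random.default_rng([0 if seed is None else seed, b])
        idx = sub.integers(0, n, size=n)
        r_b = []
        for sl in (slice(0, n1), slice(n1, n)):
            gi = idx[sl]
            r_b.append(
                _group_pfcorr_from_pooled(
                    phi,
                    grid.weights,
                    scores[gi],
                    pooled.values[gi],
                    pooled.values[gi].mean(axis=0),
                    smoother,
                    smooth.variance_floor,
                )
            )
        Ub = r_b[1] - r_b[0]
        with np.errstate(invalid="ignore"):
            exceed += np.abs(Ub[ik, il]) > obs

    pv = exceed / B
    pmat = np.ones((K, K))
    pmat[ik, il] = pv
    pmat[il, ik] = pv

    rej_idx, m0_hat, Q = fdr_adaptive_stepup(pv, alpha)
    rejected = {(int(ik[i]), int(il[i])) for i in rej_idx}
    adj = adjusted_pvalues(pv)
    adj_mat = np.ones((K, K))
    adj_mat[ik, il] = adj
    adj_mat[il, ik] = adj
    return GroupDifferenceResult(
        U=U,
        pvalues=pmat,
        rejected=rejected,
        m0_hat=m0_hat,
        Q=Q,
        alpha=alpha,
        B=B,
        seed=seed,
        roi_names=list(sample1.roi_names),
        adjusted=adj_mat,
    )


def hotelling_two_sample(
    scoresA: np.ndarray, scoresB: np.ndarray
) -> tuple[float, float, float]:
    """Classical two-sample Hotelling T^2 on score vectors.

    Returns (T^2, F statistic, p-value); the F transform uses
    (L, nA + nB - L - 1) degrees of freedom with pooled covariance.
    """
    A = np.atleast_2d(np.asarray(scoresA, dtype=float))
    Bm = np.atleast_2d(np.asarray(scoresB, dtype=float))
    if A.shape[1] != Bm.shape[1]:
        raise ValidationError("score dimensions differ")
    nA, L = A.shape
    nB = Bm.shape[0]
    if nA + nB - 2 <= L:
        raise ValidationError("too few subjects for the score dimension")
    d = A.mean(axis=0) - Bm.mean(axis=0)
    Sp = ((nA - 1) * np.cov(A, rowvar=False, ddof=1).reshape(L, L)
          + (nB - 1) * np.cov(Bm, rowvar=False, ddof=1).reshape(L, L)) / (nA + nB - 2)
    try:
        sol = np.linalg.solve(Sp, d)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "singular pooled covariance; reduce the number of components L"
        ) from exc
    T2 = float(nA * nB / (nA + nB) * d @ sol)
    F = T2 * (nA + nB - L - 1) / (L * (nA + nB - 2))
    p = float(stats.f.sf(F, L, nA + nB - L - 1))
    return T2, F, p


def bootstrap_mean_test(
    sampleA: MultivariateFunctionalSample,
    sampleB: MultivariateFunctionalSample,
    B: int = 1000,
    delta: float = 0.90,
    seed: int | None = None,
    smooth: SmoothConfig | None = None,
) -> float:
    """Distribution-free two-sample test of equal mean functions.

    mFPC scores from a pooled fit serve as finite-dimensional proxies for
    the curves; the statistic is the Hotelling-type quadratic form on the
    score mean difference, and its null distribution is obtained by
    resampling subjects from the pooled sample (which enforces equal
    means).  Returns the bootstrap p-value.
    """
    if sampleA.grid != sampleB.grid:
        raise ValidationError("groups must share the sampling grid")
    if sampleA.roi_names != sampleB.roi_names:
        raise ValidationError("groups must share the ROI set and order")
    if B < 1:
        raise ValidationError("B must be >= 1")
    nA = sampleA.n_subjects
    nB = sampleB.n_subjects
    pooled = MultivariateFunctionalSample(
        grid=sampleA.grid,
        values=np.concatenate([sampleA.values, sampleB.values], axis=0),
        group_label="pooled",
        subject_ids=list(sampleA.subject_ids) + list(sampleB.subject_ids),
        roi_names=list(sampleA.roi_names),
    )
    pdec = fit_mfpca(pooled, delta=delta, smooth=smooth)
    L = min(pdec.L, nA + nB - 3)  # keep the pooled covariance invertible
    sc = pdec.scores[:, :L]

    T2_obs, _, _ = hotelling_two_sample(sc[:nA], sc[nA:])
    n = nA + nB
    exceed = 0
    for b in range(B):
        sub = np.random.default_rng([1 if seed is None else seed + 1, b])
        idx = sub.integers(0, n, size=n)
        try:
            T2_b, _, _ = hotelling_two_sample(sc[idx[:nA]], sc[idx[nA:]])
        except ValidationError:
            continue
        exceed += T2_b >= T2_obs
    return exceed / B
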