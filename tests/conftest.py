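import numpy as np
import pytest

import pfcorr
from pfcorr import MultivariateFunctionalSample, SmoothConfig, make_trapezoid_grid

#: configuration matching the raw empirical covariance exactly (no error
#: correction, no surface smoothing) — used wherever a brute-force oracle
#: or a noiseless algebraic identity is checked.
RAW = SmoothConfig(correct_noise=False, smooth_surface=False)


def rank2_sample(n=50, K=2, J=21, lam=(2.0, 0.5), seed=0, offset=1.0):
    """Noiseless sample lying exactly in a 2-component expansion.

    The generating vector functions are quadrature-orthonormal across the
    K ROIs, so the fitted raw-covariance model must recover exactly two
    positive eigenvalues.
    """
    rng = np.random.default_rng(seed)
    grid = make_trapezoid_grid(np.linspace(0.0, 1.0, J))
    w = np.tile(grid.weights, K)
    sw = np.sqrt(w)
    M = rng.normal(size=(K * J, 2))
    Q, _ = np.linalg.qr(sw[:, None] * M)
    phi = (Q / sw[:, None]).T.reshape(2, K, J)
    xi = rng.normal(size=(n, 2)) * np.sqrt(np.asarray(lam))
    X = offset + np.einsum("ir,rkj->ikj", xi, phi)
    return MultivariateFunctionalSample(grid=grid, values=X), phi, np.asarray(lam)


@pytest.fixture
def small_sample():
    sample, _, _ = rank2_sample()
    return sample


@pytest.fixture(scope="session")
def scenario1_operator():
    spec = pfcorr.scenario_spec(1)
    return spec, pfcorr.build_covariance_operator(spec)
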