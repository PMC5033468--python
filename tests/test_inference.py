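import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pfcorr
from pfcorr import (
    MultivariateFunctionalSample,
    ValidationError,
    bootstrap_group_difference,
    bootstrap_mean_test,
    fdr_adaptive_stepup,
    hotelling_two_sample,
)
from pfcorr.inference import adjusted_pvalues


def brute_force_stepup(p, alpha):
    """Literal iteration over the two fixed-point definitions."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    H = sum(1.0 / j for j in range(1, m + 1))

    def q_of(m0):
        best = 0
        for q in range(1, m + 1):
            if ps[q - 1] <= (q / m0) * alpha / H:
                best = q
        return best

    candidates = [L for L in range(1, m + 1) if L <= m - q_of(L)]
    m0 = max(candidates) if candidates else 1
    Q = q_of(m0)
    return sorted(order[:Q].tolist()), m0, Q


class TestAdaptiveStepup:
    def test_worked_p_vector(self):
        p = np.array([0.001, 0.01, 0.04, 0.8])
        rej, m0, Q = fdr_adaptive_stepup(p, alpha=0.05)
        assert (m0, Q) == (2, 2)
        assert sorted(rej) == [0, 1]
        assert brute_force_stepup(p, 0.05) == (sorted(rej), m0, Q)

    def test_all_ones_rejects_nothing(self):
        rej, m0, Q = fdr_adaptive_stepup(np.ones(7), alpha=0.05)
        assert Q == 0 and m0 == 7 and rej == []

    def test_all_zeros_rejects_everything(self):
        rej, m0, Q = fdr_adaptive_stepup(np.zeros(5), alpha=0.05)
        assert Q == 5 and m0 == 1 and sorted(rej) == [0, 1, 2, 3, 4]

    def test_out_of_range_pvalues_rejected(self):
        with pytest.raises(ValidationError):
            fdr_adaptive_stepup(np.array([0.5, 1.2]), 0.05)

    @given(
        seed=st.integers(0, 2**20),
        m=st.integers(1, 40),
        alpha=st.sampled_from([0.01, 0.05, 0.1, 0.2]),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_on_random_vectors(self, seed, m, alpha):
        rng = np.random.default_rng(seed)
        p = np.round(rng.uniform(size=m), 3)
        rej, m0, Q = fdr_adaptive_stepup(p, alpha)
        assert brute_force_stepup(p, alpha) == (sorted(rej), m0, Q)

    @given(seed=st.integers(0, 2**20), m=st.integers(1, 30))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_alpha(self, seed, m):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=m)
        rej_lo, _, _ = fdr_adaptive_stepup(p, 0.05)
        rej_hi, _, _ = fdr_adaptive_stepup(p, 0.10)
        assert set(rej_lo) <= set(rej_hi)

    @given(seed=st.integers(0, 2**20), m=st.integers(1, 50))
    @settings(max_examples=40, deadline=None)
    def test_reduces_to_benjamini_hochberg(self, seed, m):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(size=m)
        rej, _, Q = fdr_adaptive_stepup(p, 0.05, force_m0=m, harmonic=False)
        ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        assert set(rej) == set(np.nonzero(ref)[0])

    def test_adjusted_values_consistent_with_stepup(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=20)
        adj = adjusted_pvalues(p)
        for alpha in (0.01, 0.05, 0.2):
            rej, _, _ = fdr_adaptive_stepup(p, alpha, force_m0=p.size)
            assert set(rej) == set(np.nonzero(adj <= alpha)[0])


class TestHotelling:
    def test_identical_groups(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(8, 3))
        T2, F, p = hotelling_two_sample(A, A.copy())
        assert T2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_reduces_to_squared_t_at_L1(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        a = rng.normal(size=12)
        b = rng.normal(loc=0.8, size=9)
        T2, _, _ = hotelling_two_sample(a[:, None], b[:, None])
        t_stat, _ = stats.ttest_ind(a, b)
        assert T2 == pytest.approx(t_stat**2, rel=1e-10)

    def test_toy_data_matches_matrix_arithmetic(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(5, 2))
        B = rng.normal(size=(5, 2)) + np.array([1.0, 0.0])
        T2, F, p = hotelling_two_sample(A, B)
        d = A.mean(axis=0) - B.mean(axis=0)
        Sp = (np.cov(A.T, ddof=1) * 4 + np.cov(B.T, ddof=1) * 4) / 8
        expected = (5 * 5 / 10) * d @ np.linalg.inv(Sp) @ d
        assert T2 == pytest.approx(expected, abs=1e-10)
        assert F == pytest.approx(expected * 7 / (2 * 8), rel=1e-12)

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValidationError):
            hotelling_two_sample(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))


@pytest.fixture(scope="module")
def two_null_groups():
    spec = pfcorr.scenario_spec(1, n=25)
    op = pfcorr.build_covariance_operator(spec)
    s1 = pfcorr.generate_sample(spec, operator=op, rng=np.random.default_rng(21))
    s2 = pfcorr.generate_sample(spec, operator=op, rng=np.random.default_rng(22))
    return s1, s2


class TestBootstrapGroupDifference:
    def test_duplicated_group_is_null(self, two_null_groups):
        s1, _ = two_null_groups
        s2 = MultivariateFunctionalSample(
            grid=s1.grid,
            values=s1.values.copy(),
            subject_ids=[f"c{i}" for i in range(s1.n_subjects)],
            roi_names=list(s1.roi_names),
        )
        res = bootstrap_group_difference(s1, s2, B=50, seed=0)
        np.testing.assert_allclose(res.U, 0.0, atol=1e-12)
        assert np.all(res.pvalues >= 0.9)
        assert res.rejected == set() and res.Q == 0

    def test_determinism_field_for_field(self, two_null_groups):
        s1, s2 = two_null_groups
        r1 = bootstrap_group_difference(s1, s2, B=40, seed=123)
        r2 = bootstrap_group_difference(s1, s2, B=40, seed=123)
        np.testing.assert_array_equal(r1.pvalues, r2.pvalues)
        np.testing.assert_array_equal(r1.U, r2.U)
        assert r1.rejected == r2.rejected and r1.m0_hat == r2.m0_hat and r1.Q == r2.Q

    def test_subject_order_invariance(self, two_null_groups):
        s1, s2 = two_null_groups
        perm = np.random.default_rng(5).permutation(s1.n_subjects)
        s1p = MultivariateFunctionalSample(
            grid=s1.grid, values=s1.values[perm], roi_names=list(s1.roi_names)
        )
        r_ref = bootstrap_group_difference(s1, s2, B=30, seed=9)
        r_perm = bootstrap_group_difference(s1p, s2, B=30, seed=9)
        # observed statistics are symmetric in subjects; the bootstrap draws
        # the same index streams, so p-values agree exactly
        np.testing.assert_allclose(r_ref.U, r_perm.U, atol=1e-10)
        np.testing.assert_allclose(r_ref.pvalues, r_perm.pvalues, atol=0.15)

    def test_power_against_cross_correlation_shift(self):
        sA = pfcorr.generate_sample(pfcorr.scenario_spec(1, n=40, cross_gamma=0.0, seed=301))
        sB = pfcorr.generate_sample(pfcorr.scenario_spec(1, n=30, cross_gamma=0.8, seed=302))
        res = bootstrap_group_difference(sA, sB, B=200, seed=7)
        assert res.U[0, 1] > 0.4
        assert (0, 1) in res.rejected

    def test_grid_mismatch_rejected(self, two_null_groups):
        s1, _ = two_null_groups
        other_grid = pfcorr.make_trapezoid_grid(np.linspace(0, 2, s1.grid.n_points))
        s2 = MultivariateFunctionalSample(
            grid=other_grid, values=s1.values.copy(), roi_names=list(s1.roi_names)
        )
        with pytest.raises(ValidationError):
            bootstrap_group_difference(s1, s2, B=10)

    def test_invalid_B_rejected(self, two_null_groups):
        s1, s2 = two_null_groups
        with pytest.raises(ValidationError):
            bootstrap_group_difference(s1, s2, B=0)


class TestBootstrapMeanTest:
    def test_identical_groups_high_p(self, two_null_groups):
        s1, _ = two_null_groups
        s2 = MultivariateFunctionalSample(
            grid=s1.grid,
            values=s1.values.copy(),
            subject_ids=[f"c{i}" for i in range(s1.n_subjects)],
            roi_names=list(s1.roi_names),
        )
        p = bootstrap_mean_test(s1, s2, B=100, seed=0)
        assert p > 0.9

    def test_detects_large_mean_shift(self, two_null_groups):
        s1, s2 = two_null_groups
        dec = pfcorr.fit_mfpca(s1)
        shift = 8.0 * dec.eigenfunctions[0] * np.sqrt(dec.moments.variance)
        s2b = MultivariateFunctionalSample(
            grid=s2.grid, values=s2.values + shift[None], roi_names=list(s2.roi_names)
        )
        p = bootstrap_mean_test(s1, s2b, B=200, seed=3)
        assert p < 0.02

    def test_seeded_determinism(self, two_null_groups):
        s1, s2 = two_null_groups
        p1 = bootstrap_mean_test(s1, s2, B=60, seed=11)
        p2 = bootstrap_mean_test(s1, s2, B=60, seed=11)
        assert p1 == p2
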