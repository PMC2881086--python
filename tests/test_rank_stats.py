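"""Unit and property tests for the rank-statistics core."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from domenrich import InputError, bh_adjust, mann_whitney, rho_statistic, storey_qvalues
from domenrich.rank_stats import _exact_u_counts, estimate_pi0, multiple_testing

finite_floats = st.floats(
    min_value=-1e6, max_value=1e6, allow_nan=False, allow_infinity=False
)
value_lists = st.lists(finite_floats, min_size=2, max_size=12)


class TestMannWhitney:
    @pytest.mark.parametrize(
        "domain, rest, u, p, rho",
        [
            ([4, 5, 6], [1, 2, 3], 9.0, 0.1, 1.0),  # complete separation, high
            ([1, 2, 3], [4, 5, 6], 0.0, 0.1, 0.0),  # complete separation, low
            ([5, 5], [5, 5], 2.0, 1.0, 0.5),  # identical values overlap fully
        ],
    )
    def test_small_sample_examples(self, domain, rest, u, p, rho):
        res = mann_whitney(domain, rest)
        assert res.u_statistic == u
        assert res.p_value == pytest.approx(p, abs=1e-12)
        assert res.rho == pytest.approx(rho, abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(1, 2), (3, 3), (5, 4), (6, 6), (2, 10)])
    def test_exact_count_table_sums_to_binomial(self, n1, n2):
        counts = _exact_u_counts(n1, n2)
        assert counts.size == n1 * n2 + 1
        assert counts.sum() == math.comb(n1 + n2, n1)
        # the null distribution of U is symmetric about n1*n2/2
        np.testing.assert_allclose(counts, counts[::-1])

    def test_exact_matches_scipy_on_random_tie_free_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n1, n2 = rng.integers(2, 12, size=2)
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            ours = mann_whitney(x, y)
            ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.method == "exact"
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_normal_approx_matches_scipy_with_ties(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n1, n2 = rng.integers(5, 40, size=2)
            x = rng.integers(0, 6, size=n1).astype(float)
            y = rng.integers(0, 6, size=n2).astype(float)
            if np.all(np.concatenate([x, y]) == x[0]):
                continue
            ours = mann_whitney(x, y)
            ref = scipy.stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            )
            assert ours.method == "normal_approx"
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_tie_free_groups_use_normal_approximation(self):
        rng = np.random.default_rng(13)
        res = mann_whitney(rng.normal(size=40), rng.normal(size=60))
        assert res.method == "normal_approx"

    def test_exact_and_normal_agree_near_threshold(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            x = rng.normal(0.3, 1, size=25)
            y = rng.normal(0, 1, size=60)
            exact = mann_whitney(x, y, method="exact")
            approx = mann_whitney(x, y, method="normal_approx")
            assert abs(exact.p_value - approx.p_value) <= 0.01

    def test_permutation_mode_is_seeded_and_close_to_exact(self):
        rng = np.random.default_rng(15)
        x, y = rng.normal(1.0, 1, size=8), rng.normal(size=12)
        p1 = mann_whitney(x, y, method="permutation", rng=5, n_permutations=20000)
        p2 = mann_whitney(x, y, method="permutation", rng=5, n_permutations=20000)
        exact = mann_whitney(x, y, method="exact")
        assert p1.p_value == p2.p_value
        assert abs(p1.p_value - exact.p_value) < 0.02

    def test_permutation_mode_handles_small_tied_sets(self):
        res = mann_whitney([3, 3, 5], [1, 3, 2, 2], method="permutation", rng=0)
        assert res.method == "permutation"
        assert 0.0 < res.p_value <= 1.0

    def test_moderate_shifted_groups_match_permutation_oracle(self):
        """Exact p for a 25-vs-200 location shift agrees with a large
        Monte-Carlo permutation estimate within its sampling band."""
        rng = np.random.default_rng(16)
        x = rng.normal(0.7, 1, size=25)
        y = rng.normal(0.0, 1, size=200)
        res = mann_whitney(x, y)
        assert res.method == "exact"
        n_rep = 200_000
        oracle = mann_whitney(x, y, method="permutation", rng=1, n_permutations=n_rep)
        band = 4 * math.sqrt(res.p_value * (1 - res.p_value) / n_rep) + 1e-6
        assert abs(res.p_value - oracle.p_value) <= band

    def test_all_identical_values_give_p_one_and_half_rho(self):
        res = mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0
        assert res.rho == 0.5

    @pytest.mark.parametrize(
        "domain, rest",
        [([], [1, 2]), ([1, 2], []), ([1], [2]), ([np.nan, 1], [2, 3])],
    )
    def test_invalid_groups_raise(self, domain, rest):
        with pytest.raises(InputError):
            mann_whitney(domain, rest)

    def test_exact_method_rejects_ties(self):
        with pytest.raises(InputError):
            mann_whitney([1, 2, 2], [3, 4], method="exact")

    @given(value_lists, value_lists)
    def test_two_sided_p_is_symmetric_in_the_groups(self, a, b):
        ra, rb = mann_whitney(a, b), mann_whitney(b, a)
        assert ra.p_value == pytest.approx(rb.p_value, rel=1e-9)
        assert 0.0 <= ra.u_statistic <= ra.n_domain * ra.n_rest
        assert 0.0 < ra.p_value <= 1.0


class TestRho:
    @pytest.mark.parametrize(
        "domain, rest, expected",
        [
            ([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], 0.5),
            ([4, 5, 6], [1, 2, 3], 1.0),
            ([1, 2, 3], [4, 5, 6], 0.0),
        ],
    )
    def test_endpoint_behaviour(self, domain, rest, expected):
        assert rho_statistic(domain, rest) == expected

    def test_matches_pairwise_counting_definition(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            x = rng.integers(0, 5, size=rng.integers(2, 9)).astype(float)
            y = rng.integers(0, 5, size=rng.integers(2, 9)).astype(float)
            wins = sum(1.0 for a in x for b in y if a > b)
            ties = sum(1.0 for a in x for b in y if a == b)
            assert rho_statistic(x, y) == pytest.approx(
                (wins + 0.5 * ties) / (len(x) * len(y)), abs=1e-12
            )

    @given(value_lists, value_lists)
    def test_antisymmetry(self, a, b):
        assert rho_statistic(a, b) == pytest.approx(
            1.0 - rho_statistic(b, a), abs=1e-12
        )

    @given(value_lists, value_lists, st.floats(min_value=0.0, max_value=100.0))
    def test_shifting_the_domain_up_never_decreases_rho(self, a, b, shift):
        base = rho_statistic(a, b)
        shifted = rho_statistic([v + shift for v in a], b)
        assert shifted >= base - 1e-12

    def test_empty_group_raises(self):
        with pytest.raises(InputError):
            rho_statistic([], [1.0])


class TestMultipleTesting:
    def test_bh_step_up_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.002, 0.01, 0.03, 0.04]), [0.008, 0.02, 0.04, 0.04]
        )

    def test_bh_single_p_is_identity(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_bh_matches_statsmodels(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 200))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref, rtol=1e-12)

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=60))
    def test_bh_dominates_raw_p_and_is_capped(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_bh_stable_under_tied_p_values(self):
        p = [0.02, 0.01, 0.02, 0.5]
        adj = bh_adjust(p)
        assert adj[0] == adj[2]

    def test_storey_with_pi0_one_equals_bh_exactly(self):
        rng = np.random.default_rng(32)
        p = rng.uniform(1e-6, 1, size=500)
        q, pi0 = storey_qvalues(p, pi0=1.0)
        assert pi0 == 1.0
        assert np.array_equal(q, bh_adjust(p))

    def test_small_families_fall_back_to_pi0_one(self):
        p = np.linspace(0.01, 0.99, 50)
        q, pi0 = storey_qvalues(p)  # 50 < default pi0_min_tests
        assert pi0 == 1.0
        assert np.array_equal(q, bh_adjust(p))

    def test_pi0_on_uniform_null_is_near_one(self):
        for seed in (1, 2, 3, 4, 5):
            p = np.random.default_rng(seed).uniform(1e-12, 1, size=1000)
            assert 0.85 <= estimate_pi0(p) <= 1.0

    def test_signal_mixture_lowers_pi0_and_q_below_bh(self):
        rng = np.random.default_rng(34)
        p = np.concatenate(
            [rng.uniform(1e-12, 1, size=800), rng.uniform(1e-8, 1e-3, size=200)]
        )
        q, pi0 = storey_qvalues(p)
        assert pi0 < 0.95
        assert np.all(q <= bh_adjust(p) + 1e-15)

    def test_bundle_carries_consistent_columns(self):
        rng = np.random.default_rng(35)
        p = rng.uniform(1e-6, 1, size=300)
        res = multiple_testing(p)
        assert np.all(res.bh_adjusted >= res.p_values)
        assert np.all(res.q_values <= res.bh_adjusted + 1e-15)
        assert 0.0 < res.pi0_estimate <= 1.0
        # monotone non-decreasing when ordered by p
        order = np.argsort(res.p_values)
        assert np.all(np.diff(res.bh_adjusted[order]) >= -1e-15)
        assert np.all(np.diff(res.q_values[order]) >= -1e-15)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.2], [], [np.nan]])
    def test_out_of_range_p_values_raise(self, bad):
        with pytest.raises(InputError):
            bh_adjust(bad)
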