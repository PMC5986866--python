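import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_tau_b
from walshscape import (
    expectation_orders,
    g_test_uniformity,
    holm_correct,
    kendall_tau_b,
    permutation_test,
)
from walshscape.stats import (
    DEFAULT_G_TEST_EDGES,
    _null_taus_sampled,
    g_test_pvalue,
    significance_stars,
)


class TestExpectationOrders:
    @pytest.mark.parametrize(
        "L,expected",
        [(2, [0, 1, 1, 2]), (3, [0, 1, 1, 1, 2, 2, 2, 3])],
    )
    def test_binomial_multiplicities(self, L, expected):
        np.testing.assert_array_equal(expectation_orders(L), expected)

    def test_truncation_keeps_the_lowest_orders(self):
        np.testing.assert_array_equal(expectation_orders(3, 5), [0, 1, 1, 1, 2])

    def test_range_checks(self):
        with pytest.raises(ValueError):
            expectation_orders(0)
        with pytest.raises(ValueError):
            expectation_orders(3, 9)


class TestKendallTauB:
    def test_hand_counted_case(self):
        # P=3, Q=1, T_x=1, T_y=1 -> 2/sqrt(25) = 0.4
        assert kendall_tau_b([0, 1, 1, 2], [0, 1, 2, 1]) == pytest.approx(0.4)

    def test_perfect_concordance_and_reversal(self):
        assert kendall_tau_b([0, 1, 1, 2], [0, 1, 1, 2]) == pytest.approx(1.0)
        assert kendall_tau_b([0, 1, 2], [2, 1, 0]) == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau_b([1, 1, 1], [0, 1, 2])

    @given(st.integers(0, 2**31), st.integers(4, 24))
    @settings(max_examples=40, deadline=None)
    def test_agrees_with_brute_force_pair_counting(self, seed, n):
        r = np.random.default_rng(seed)
        x = r.integers(0, 4, size=n)
        y = r.integers(0, 4, size=n)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        assert kendall_tau_b(x, y) == pytest.approx(brute_tau_b(x, y), abs=1e-12)

    @given(st.integers(0, 2**31))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_monotone_relabeling_invariance(self, seed):
        r = np.random.default_rng(seed)
        x = r.integers(0, 5, size=12)
        y = r.integers(0, 5, size=12)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        t = kendall_tau_b(x, y)
        assert kendall_tau_b(y, x) == pytest.approx(t, abs=1e-12)
        assert kendall_tau_b(x**3 + 2 * x, y) == pytest.approx(t, abs=1e-12)


class TestPermutationTest:
    def test_exact_enumeration_for_tiny_landscape(self):
        """12 of the 144 permutation pairs of [0,1,1,2] are perfectly concordant."""
        res = permutation_test([0, 1, 1, 2], L=2, method="exact")
        assert res.tau_b == pytest.approx(1.0)
        assert res.p_uncorrected == pytest.approx(1 / 12)

    def test_anticorrelated_observation_has_large_p(self):
        obs = expectation_orders(3)[::-1]
        res = permutation_test(obs, L=3, n_reps=2000, seed=3)
        assert res.tau_b < 0
        assert res.p_uncorrected > 0.5

    def test_same_seed_is_bit_reproducible(self):
        obs = [0, 2, 1, 1, 2, 2, 3, 1]
        a = permutation_test(obs, L=3, n_reps=5000, seed=11)
        b = permutation_test(obs, L=3, n_reps=5000, seed=11)
        assert a.tau_b == b.tau_b and a.p_uncorrected == b.p_uncorrected

    def test_truncated_observation_uses_expectation_prefix(self):
        res = permutation_test([0, 1, 1, 1], L=3, n_reps=500, seed=0)
        assert res.n_terms == 4 and res.j == 4
        assert res.tau_b == pytest.approx(1.0)

    def test_sampled_null_matches_exact_distribution(self):
        taus = _null_taus_sampled(
            expectation_orders(2), 20_000, np.random.default_rng(0)
        )
        assert np.mean(taus >= 1.0 - 1e-12) == pytest.approx(1 / 12, abs=0.01)
        assert np.abs(taus.mean()) < 0.02

    def test_rejects_degenerate_observations(self):
        with pytest.raises(ValueError):
            permutation_test([1], L=2)
        with pytest.raises(ValueError):
            permutation_test([1, 1, 1], L=2, n_reps=10)


class TestHolm:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_correct([0.01]), [0.01])

    def test_textbook_two_tests(self):
        np.testing.assert_allclose(holm_correct([0.01, 0.04]), [0.02, 0.04])

    def test_capping_and_monotonicity(self):
        np.testing.assert_allclose(holm_correct([0.5, 0.6, 0.9]), [1.0, 1.0, 1.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            holm_correct([])


class TestGTest:
    def test_uniform_counts_give_zero(self):
        p = [1 / 12, 0.25, 0.4, 0.55, 0.7, 0.9]
        g, df = g_test_uniformity(p, bin_edges=np.linspace(0, 1, 7))
        assert g == pytest.approx(0.0)
        assert df == 5

    def test_hand_arithmetic_two_bins(self):
        g, df = g_test_uniformity([0.2, 0.3], bin_edges=[0, 0.5, 1.0])
        assert g == pytest.approx(2 * 2 * np.log(2))
        assert df == 1
        assert 0 < g_test_pvalue(g, df) < 1

    def test_default_edges_are_log_decades(self):
        assert len(DEFAULT_G_TEST_EDGES) == 7
        g, df = g_test_uniformity([0.0, 1e-5, 0.5], )
        assert df == 5

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            g_test_uniformity([1.5])
        with pytest.raises(ValueError):
            g_test_uniformity([0.5], bin_edges=[0.0, 1.0])


def test_significance_stars_thresholds():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.2) == ""
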