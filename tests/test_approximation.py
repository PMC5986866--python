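import numpy as np
import pytest

from oracles import all_subset_residuals
from walshscape import (
    Landscape,
    Spectrum,
    best_m_approximation,
    per_order_summary,
    rank_terms,
    residual_sequence,
    truncate_by_experimental_variance,
    walsh_forward,
    walsh_inverse,
)
from walshscape.approximation import ApproxSequence


class TestRankTerms:
    def test_simple_ranking(self):
        idx, orders = rank_terms(Spectrum(L=1, E=[3.0, -1.0]))
        np.testing.assert_array_equal(idx, [0, 1])
        np.testing.assert_array_equal(orders, [0, 1])

    def test_all_tied_keeps_canonical_order(self):
        idx, orders = rank_terms(Spectrum(L=2, E=[0.25, -0.25, -0.25, 0.25]))
        np.testing.assert_array_equal(idx, [0, 1, 2, 3])
        np.testing.assert_array_equal(orders, [0, 1, 1, 2])

    def test_zeros_trail_in_canonical_order(self):
        idx, _ = rank_terms(Spectrum(L=2, E=[0.0, 5.0, 0.0, 0.0]))
        np.testing.assert_array_equal(idx, [1, 0, 2, 3])

    def test_arithmetic_noise_on_exact_zeros_is_snapped(self):
        E = np.array([1.0, 0.5, 3e-17, -2e-17])
        idx, _ = rank_terms(Spectrum(L=2, E=E))
        np.testing.assert_array_equal(idx, [0, 1, 2, 3])


class TestBestM:
    def test_extremes(self, random_landscape):
        ls = random_landscape(3)
        sp = walsh_forward(ls)
        np.testing.assert_allclose(best_m_approximation(sp, 8).W, ls.W, atol=1e-10)
        np.testing.assert_allclose(best_m_approximation(sp, 0).W, 0.0)
        with pytest.raises(ValueError):
            best_m_approximation(sp, 9)

    def test_best_m_minimizes_residual_over_all_subsets(self, rng):
        """Exhaustive check of the optimality guarantee at L=2."""
        for _ in range(5):
            ls = Landscape(L=2, W=rng.normal(size=4))
            sp = walsh_forward(ls)
            for m in range(5):
                approx = best_m_approximation(sp, m)
                resid = np.sum((ls.W - approx.W) ** 2)
                alternatives = all_subset_residuals(sp.E, m)
                assert resid <= 4 * min(alternatives) + 1e-10


class TestResidualSequence:
    def test_mean_term_explains_no_variance(self):
        seq = residual_sequence(Landscape(L=1, W=[2.0, 4.0]))
        np.testing.assert_allclose(seq.resid_fraction, [1.0, 1.0, 0.0], atol=1e-12)

    def test_additive_landscape_explained_by_mean_plus_main_effects(self):
        E = np.zeros(8)
        E[0], E[1], E[2], E[4] = 1.0, 0.5, -0.3, 0.2
        ls = walsh_inverse(Spectrum(L=3, E=E))
        seq = residual_sequence(ls)
        assert seq.resid_fraction[4] == pytest.approx(0.0, abs=1e-12)
        assert seq.resid_fraction[3] > 0

    def test_monotone_between_one_and_zero(self, random_landscape):
        seq = residual_sequence(random_landscape(4))
        assert seq.resid_fraction[0] == 1.0
        assert seq.resid_fraction[-1] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(seq.resid_fraction) <= 1e-12)

    def test_term_reductions_sum_to_one(self, random_landscape):
        seq = residual_sequence(random_landscape(3))
        assert seq.term_reduction.sum() == pytest.approx(1.0)
        assert seq.term_reduction[seq.ranked_indices == 0] == 0.0

    def test_constant_landscape_rejected(self):
        with pytest.raises(ValueError):
            residual_sequence(Landscape(L=1, W=[1.0, 1.0]))


class TestTruncation:
    def _seq(self, resid):
        L = int(np.log2(len(resid) - 1))
        return ApproxSequence(
            L=L,
            ranked_indices=np.arange(2**L),
            ranked_orders=np.zeros(2**L, dtype=int),
            resid_fraction=np.asarray(resid, dtype=float),
            m_star=2**L,
        )

    def test_threshold_crossing(self):
        seq = self._seq([1.0, 0.4, 0.1, 0.05, 0.0])
        assert truncate_by_experimental_variance(seq, 0.15) == 2

    def test_zero_threshold_keeps_terms_until_exact_zero(self):
        seq = self._seq([1.0, 0.4, 0.0, 0.0, 0.0])
        assert truncate_by_experimental_variance(seq, 0.0) == 2

    def test_threshold_above_total_variance_warns_and_keeps_nothing(self):
        seq = self._seq([1.0, 0.4, 0.1, 0.05, 0.0])
        with pytest.warns(UserWarning):
            assert truncate_by_experimental_variance(seq, 1.5) == 0


class TestPerOrderSummary:
    def test_parseval_arithmetic(self):
        sp = Spectrum(L=2, E=[0.5, 0.4, 0.2, 0.1])
        seq = residual_sequence(walsh_inverse(sp))
        table = per_order_summary(seq, sp).set_index("order")
        denom = 0.4**2 + 0.2**2 + 0.1**2
        assert table.loc[1, "aggregate_reduction"] == pytest.approx(
            (0.4**2 + 0.2**2) / denom
        )
        assert table.loc[2, "aggregate_reduction"] == pytest.approx(0.1**2 / denom)
        assert table.loc[1, "n_terms"] == 2

    def test_additive_landscape_attributes_everything_to_order_one(self):
        E = np.zeros(8)
        E[0], E[1], E[2], E[4] = 1.0, 0.5, -0.3, 0.2
        sp = Spectrum(L=3, E=E)
        seq = residual_sequence(walsh_inverse(sp))
        table = per_order_summary(seq, sp).set_index("order")
        assert table.loc[1, "aggregate_reduction"] == pytest.approx(1.0)
        assert table.loc[0, "aggregate_reduction"] == 0.0

    def test_truncation_limits_contributing_terms(self):
        sp = Spectrum(L=2, E=[0.5, 0.4, 0.2, 0.1])
        seq = residual_sequence(walsh_inverse(sp))
        seq.m_star = 2  # keep mean + largest main effect only
        table = per_order_summary(seq, sp).set_index("order")
        assert 2 not in table.index
        assert table.loc[1, "n_terms"] == 1
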