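"""Rank statistics for the declining-influence hypothesis.

If the influence of interaction terms on landscape topography declines with
epistatic order, then sorting the Walsh coefficients by descending magnitude
should produce an order sequence close to the combinatoric expectation

    0, 1 (x L), 2 (x C(L,2)), ..., L          (one k for every k-subset)

Agreement is measured by Kendall's tau-b (ties in both vectors are expected
and corrected for), and significance by a one-tailed permutation test whose
null draws are tau-b between two independent random permutations of the
expectation multiset.  Across a collection of studies, a Holm step-down
correction controls the family-wise error rate and a G-test against the
uniform distribution summarises the joint skew of the uncorrected P values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .transform import subset_orders

__all__ = [
    "ExpectationVector",
    "StudyResult",
    "expectation_orders",
    "kendall_tau_b",
    "permutation_test",
    "holm_correct",
    "g_test_uniformity",
    "significance_stars",
    "DEFAULT_G_TEST_EDGES",
    "DEFAULT_N_REPS",
]

DEFAULT_N_REPS = 100_000

# Log-decade bins on (0, 1]; the lowest bin is closed, [0, 1e-5], so that
# P values reported only as an upper bound "< 1/n_reps" (stored as 0) land in it.
DEFAULT_G_TEST_EDGES = (0.0, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0)


@dataclass
class ExpectationVector:
    """The sorted multiset of epistatic orders for L loci (possibly truncated)."""

    L: int
    orders: np.ndarray


def expectation_orders(L: int, n: int | None = None) -> np.ndarray:
    """Sorted orders 0..L with multiplicity C(L, k); optionally the first n.

    Truncation keeps the *first* n entries: the lowest orders, mirroring the
    discard of the trailing j entries when noisy terms are dropped.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    full = np.sort(subset_orders(L))
    if n is None:
        return full
    if not 0 < n <= 2**L:
        raise ValueError(f"n must be in (0, {2**L}]")
    return full[:n]


def kendall_tau_b(x, y) -> float:
    """Kendall's tau-b between two integer (or real) vectors with ties.

    tau_b = (P - Q) / sqrt((P + Q + T_x)(P + Q + T_y)) with P/Q the
    concordant/discordant pair counts and T the single-variable tie counts.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau_b undefined for a constant vector")
    return float(scipy.stats.kendalltau(x, y, variant="b").statistic)


@dataclass
class StudyResult:
    """Outcome of the order-sequence test for one landscape."""

    tau_b: float
    n_terms: int
    p_uncorrected: float
    n_reps: int
    seed: int | None
    m_star: int
    j: int
    p_corrected: float | None = None
    exact: bool = False

    @property
    def p_display(self) -> str:
        """P value formatted as in study reports; 0 prints as an upper bound."""
        if self.p_uncorrected == 0 and not self.exact:
            return f"< {1 / self.n_reps:g}"
        return f"{self.p_uncorrected:.5f}"


def _pair_stat_matrix(v: np.ndarray) -> np.ndarray:
    """sign(v_j - v_i) over all pairs, as int8."""
    return np.sign(v[:, None] - v[None, :]).astype(np.int8)


def _tie_pairs(v: np.ndarray) -> int:
    _, counts = np.unique(v, return_counts=True)
    return int(np.sum(counts * (counts - 1)) // 2)


def _null_taus_sampled(
    multiset: np.ndarray, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """tau-b between two independent random permutations of ``multiset``.

    Both sides share the multiset, so the tie-corrected denominator is the
    constant ``n0 - n1`` and only the concordance count S = P - Q varies;
    S is accumulated with vectorised pairwise sign products in chunks.
    """
    n = multiset.size
    n0 = n * (n - 1) // 2
    denom = n0 - _tie_pairs(multiset)
    taus = np.empty(n_reps)
    chunk = max(1, min(n_reps, 4_000_000 // (n * n)))
    base = np.tile(multiset, (chunk, 1))
    done = 0
    while done < n_reps:
        c = min(chunk, n_reps - done)
        xs = rng.permuted(base[:c], axis=1)
        ys = rng.permuted(base[:c], axis=1)
        sx = np.sign(xs[:, :, None] - xs[:, None, :]).astype(np.int8)
        sy = np.sign(ys[:, :, None] - ys[:, None, :]).astype(np.int8)
        s = np.einsum("rij,rij->r", sx, sy, dtype=np.int64) // 2
        taus[done : done + c] = s / denom
        done += c
    return taus


def _null_taus_exact(multiset: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All distinct permutation pairs: (tau values, pair counts)."""
    from sympy.utilities.iterables import multiset_permutations

    perms = [np.array(p) for p in multiset_permutations(sorted(multiset))]
    taus = np.array(
        [kendall_tau_b(a, b) for a in perms for b in perms]
    )
    return taus, np.ones_like(taus)


def permutation_test(
    observed_orders,
    L: int,
    n_reps: int = DEFAULT_N_REPS,
    seed: int | None = 0,
    *,
    method: str = "sample",
) -> StudyResult:
    """One-tailed permutation test of the declining-influence hypothesis.

    The empirical tau-b is computed between ``observed_orders`` (the orders of
    the retained terms, largest magnitude first) and the equal-length prefix
    of the combinatoric expectation.  The null distribution is tau-b between
    two independent uniformly random permutations of that expectation prefix;
    P is the fraction of null draws >= the empirical value (reported as 0,
    i.e. "< 1/n_reps", when none are).

    ``method="exact"`` enumerates all distinct permutation pairs instead of
    sampling (feasible only for very short vectors).
    """
    observed = np.asarray(observed_orders)
    n = observed.size
    if n < 2:
        raise ValueError("need at least two retained terms")
    expect = expectation_orders(L, n)
    emp = kendall_tau_b(observed, expect)

    if method == "exact":
        taus, weights = _null_taus_exact(expect)
        p = float(np.sum(weights[taus >= emp - 1e-12]) / weights.sum())
        n_eff = taus.size
        exact = True
    elif method == "sample":
        rng = np.random.default_rng(seed)
        taus = _null_taus_sampled(expect, n_reps, rng)
        p = float(np.count_nonzero(taus >= emp - 1e-12) / n_reps)
        n_eff = n_reps
        exact = False
    else:
        raise ValueError(f"unknown method {method!r}")

    return StudyResult(
        tau_b=emp,
        n_terms=n,
        p_uncorrected=p,
        n_reps=n_eff,
        seed=seed,
        m_star=n,
        j=2**L - n,
        exact=exact,
    )


def holm_correct(p_values) -> np.ndarray:
    """Holm step-down adjusted P values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no P values to correct")
    if np.any((p <= 0) & (p != 0)) or np.any(p > 1) or np.any(p < 0):
        raise ValueError("P values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def g_test_uniformity(
    p_values, bin_edges=DEFAULT_G_TEST_EDGES
) -> tuple[float, int]:
    """Likelihood-ratio (G) test of P values against the uniform distribution.

    P values are binned on ``bin_edges`` (lowest bin closed at both ends so
    that "< bound" entries stored as 0 are counted; upper edges inclusive);
    expected counts are ``n * bin width``.  Returns (G, df) with
    df = number of bins - 1; refer G to the chi-squared distribution.
    """
    p = np.asarray(p_values, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 3:
        raise ValueError("need at least two bins")
    if np.any(np.diff(edges) <= 0) or edges[-1] > 1 or edges[0] < 0:
        raise ValueError("bin edges must be increasing within [0, 1]")
    if np.any(p < edges[0]) or np.any(p > edges[-1]):
        raise ValueError("P value outside the binned range")
    obs = np.empty(edges.size - 1, dtype=int)
    obs[0] = np.count_nonzero(p <= edges[1])
    for b in range(1, edges.size - 1):
        obs[b] = np.count_nonzero((p > edges[b]) & (p <= edges[b + 1]))
    n = p.size
    expected = n * np.diff(edges) / (edges[-1] - edges[0])
    nz = obs > 0
    g = float(2.0 * np.sum(obs[nz] * np.log(obs[nz] / expected[nz])))
    return g, int(edges.size - 2)


def g_test_pvalue(g: float, df: int) -> float:
    """Chi-squared tail probability for a G statistic."""
    return float(scipy.stats.chi2.sf(g, df))


def significance_stars(p_corrected: float) -> str:
    """Star notation on corrected P: *** <=0.001, ** <=0.01, * <=0.05."""
    if p_corrected <= 0.001:
        return "***"
    if p_corrected <= 0.01:
        return "**"
    if p_corrected <= 0.05:
        return "*"
    return ""
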