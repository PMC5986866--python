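"""Best-m subsetting approximations of a landscape.

Zeroing all but the m largest-magnitude Walsh coefficients and inverting the
transform yields, for every m, the m-parameter model with the smallest
sum-of-squares distance to the data (a consequence of orthogonality).  The
residual variance of the best-m model, expressed as a fraction of the
landscape's variance about its mean, is by Parseval the sum of squared
*excluded* non-zeroth coefficients over the sum of squared non-zeroth
coefficients; the order-0 (mean) coefficient never explains any variance
about the mean.

When an experimental-variance estimate is available the ranked sequence is
truncated at the first m whose remaining model variance falls below it, and
the discarded terms are dropped from downstream order statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import Landscape
from .transform import Spectrum, fwht, walsh_forward

__all__ = [
    "ApproxSequence",
    "rank_terms",
    "best_m_approximation",
    "residual_sequence",
    "truncate_by_experimental_variance",
    "per_order_summary",
]

# Relative magnitude below which a coefficient is treated as an exact zero for
# ranking.  Analytically-zero coefficients (e.g. all order>=2 terms of an
# additive landscape) can carry ~1e-16 arithmetic noise that would otherwise
# scramble the tie order and make ranked-order statistics irreproducible.
ZERO_SNAP_RTOL = 1e-12


def rank_terms(sp: Spectrum) -> tuple[np.ndarray, np.ndarray]:
    """Sort subset indices by descending |coefficient|.

    Ties (including coefficients that are zero to within ``ZERO_SNAP_RTOL``
    of the largest magnitude) are broken by ascending canonical subset index,
    so the ranking is deterministic.

    Returns
    -------
    ranked_indices, ranked_orders : ndarray
        A permutation of ``0..2**L-1`` and the epistatic order of each entry.
    """
    mag = np.abs(sp.E).astype(float)
    if mag.max() > 0:
        mag[mag < ZERO_SNAP_RTOL * mag.max()] = 0.0
    ranked = np.lexsort((np.arange(mag.size), -mag))
    return ranked, sp.orders[ranked]


def best_m_approximation(sp: Spectrum, m: int) -> Landscape:
    """Landscape rebuilt from the m top-ranked coefficients (the rest zeroed)."""
    n = 2**sp.L
    if not 0 <= m <= n:
        raise ValueError(f"m must be in [0, {n}]")
    ranked, _ = rank_terms(sp)
    keep = np.zeros(n, dtype=bool)
    keep[ranked[:m]] = True
    return Landscape(L=sp.L, W=fwht(np.where(keep, sp.E, 0.0)))


@dataclass
class ApproxSequence:
    """The full best-m sequence of a landscape.

    ``resid_fraction[m]`` is the residual variance of the best-m model as a
    fraction of the landscape variance about its mean, for m = 0..2**L.
    ``m_star`` is the number of retained terms after truncation by
    experimental variance (``2**L`` when no threshold was applied).
    """

    L: int
    ranked_indices: np.ndarray
    ranked_orders: np.ndarray
    resid_fraction: np.ndarray
    m_star: int
    exp_var_fraction: float | None = None
    term_reduction: np.ndarray = field(default=None, repr=False)

    @property
    def j(self) -> int:
        """Number of trailing terms discarded by truncation."""
        return 2**self.L - self.m_star

    @property
    def observed_orders(self) -> np.ndarray:
        """Epistatic orders of the retained terms, in rank order."""
        return self.ranked_orders[: self.m_star]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "m": np.arange(1, 2**self.L + 1),
                "subset": [
                    format(k, f"0{self.L}b") for k in self.ranked_indices
                ],
                "order": self.ranked_orders,
                "reduction": self.term_reduction,
                "resid_fraction": self.resid_fraction[1:],
                "retained": np.arange(1, 2**self.L + 1) <= self.m_star,
            }
        )


def truncate_by_experimental_variance(
    seq: ApproxSequence, exp_var_fraction: float
) -> int:
    """Smallest m whose residual-variance fraction falls below the threshold.

    The ``j = 2**L - m_star`` lowest-ranked terms are considered unresolvable
    against measurement noise and are discarded from order statistics.
    """
    if exp_var_fraction < 0:
        raise ValueError("exp_var_fraction must be nonnegative")
    below = np.nonzero(seq.resid_fraction < exp_var_fraction)[0]
    if below.size == 0:
        # threshold 0 (or unreachable): keep every term
        below = np.nonzero(seq.resid_fraction <= exp_var_fraction)[0]
        if below.size == 0:
            return 2**seq.L
    m_star = int(below[0])
    if m_star == 0:
        warnings.warn(
            "experimental variance exceeds total model variance; no term retained",
            stacklevel=2,
        )
    return m_star


def residual_sequence(
    ls: Landscape, exp_var_fraction: float | None = None
) -> ApproxSequence:
    """Rank the Walsh terms of ``ls`` and trace best-m residual variance.

    Parseval turns the residual sum of squares of the best-m model into a sum
    of squared excluded coefficients, so no model is ever reconstructed
    explicitly.  A constant landscape has no variance to explain and raises.
    """
    sp = walsh_forward(ls)
    ranked, ranked_orders = rank_terms(sp)
    sq = sp.E[ranked] ** 2
    sq[ranked == 0] = 0.0  # the mean term explains no variance about the mean
    total = sq.sum()
    if total == 0:
        raise ValueError("constant landscape: residual fractions undefined")
    reduction = sq / total
    resid = np.empty(2**ls.L + 1)
    resid[0] = 1.0
    resid[1:] = 1.0 - np.cumsum(reduction)
    np.clip(resid, 0.0, None, out=resid)
    resid[-1] = 0.0
    seq = ApproxSequence(
        L=ls.L,
        ranked_indices=ranked,
        ranked_orders=ranked_orders,
        resid_fraction=resid,
        m_star=2**ls.L,
        exp_var_fraction=exp_var_fraction,
        term_reduction=reduction,
    )
    if exp_var_fraction is not None:
        seq.m_star = truncate_by_experimental_variance(seq, exp_var_fraction)
    return seq


def per_order_summary(seq: ApproxSequence, sp: Spectrum) -> pd.DataFrame:
    """Aggregate, count and mean residual-variance reduction per order.

    Only terms retained after truncation (rank < m_star) contribute.  Orders
    with no retained term are omitted.
    """
    rows = []
    retained_orders = seq.ranked_orders[: seq.m_star]
    retained_reduction = seq.term_reduction[: seq.m_star]
    for order in range(sp.L + 1):
        mask = retained_orders == order
        count = int(mask.sum())
        if count == 0:
            continue
        agg = float(retained_reduction[mask].sum())
        rows.append(
            {
                "order": order,
                "aggregate_reduction": agg,
                "n_terms": count,
                "mean_reduction": agg / count,
            }
        )
    return pd.DataFrame(rows)
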