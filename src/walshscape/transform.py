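"""Fourier-Walsh decomposition of fitness landscapes.

The ``2**L`` fitness values of a complete biallelic landscape are an
orthogonal linear combination of ``2**L`` interaction coefficients, one per
subset of loci:

    E = (1 / 2**L) * Psi @ W        (forward)
    W = Psi @ E                     (inverse)

where ``Psi`` is the Sylvester-ordered Hadamard matrix,
``Psi[j, k] = (-1)**popcount(j & k)``, so ``Psi @ Psi = 2**L * I``.  The
coefficient at subset index ``k`` measures the background-averaged
interaction among the loci whose bits are set in ``k``; its *epistatic order*
is ``popcount(k)`` (order 0 is the landscape mean, order 1 the main effects).

Coefficient signs depend on which allele is labelled 0 at each locus; all
magnitudes and orders — and hence every downstream statistic — do not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "Spectrum",
    "FourierSpectrum",
    "hadamard_matrix",
    "walsh_forward",
    "walsh_inverse",
    "epistatic_order",
    "subset_orders",
    "fourier_spectrum",
    "fwht",
]

from .landscape import Landscape


def hadamard_matrix(L: int) -> np.ndarray:
    """Sylvester Hadamard matrix of size ``2**L``; entry (j,k) = (-1)**popcount(j&k)."""
    if L < 0:
        raise ValueError("L must be >= 0")
    return scipy.linalg.hadamard(2**L, dtype=float)


def fwht(x: np.ndarray) -> np.ndarray:
    """In-place-free fast Walsh-Hadamard transform (Sylvester order), O(n log n).

    Returns ``Psi @ x`` without forming the matrix.  Bit-identical with the
    explicit matrix product only to floating round-off; the matrix product is
    the reference in the test suite.
    """
    x = np.asarray(x, dtype=float).copy()
    n = x.shape[0]
    if n & (n - 1) or n == 0:
        raise ValueError("length must be a power of two")
    h = 1
    while h < n:
        for start in range(0, n, 2 * h):
            a = x[start : start + h].copy()
            b = x[start + h : start + 2 * h].copy()
            x[start : start + h] = a + b
            x[start + h : start + 2 * h] = a - b
        h *= 2
    return x


def epistatic_order(k: int, L: int | None = None) -> int:
    """Epistatic order of subset index ``k``: the number of interacting loci."""
    if k < 0 or (L is not None and k >= 2**L):
        raise ValueError(f"subset index {k} out of range")
    return int(bin(k).count("1"))


def subset_orders(L: int) -> np.ndarray:
    """Vector of popcounts for all subset indices 0..2**L-1 in canonical order."""
    orders = np.zeros(2**L, dtype=int)
    for b in range(L):
        orders[(np.arange(2**L) >> b) & 1 == 1] += 1
    return orders


@dataclass
class Spectrum:
    """Walsh interaction coefficients of a landscape, in canonical subset order."""

    L: int
    E: np.ndarray

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        if self.E.shape != (2**self.L,):
            raise ValueError(f"E must have length 2**L = {2**self.L}")

    @property
    def orders(self) -> np.ndarray:
        return subset_orders(self.L)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "subset": [format(k, f"0{self.L}b") for k in range(2**self.L)],
                "order": self.orders,
                "coefficient": self.E,
            }
        )


@dataclass
class FourierSpectrum:
    """Sum of squared interaction coefficients at each order 0..L."""

    per_order_ss: np.ndarray

    def __post_init__(self) -> None:
        self.per_order_ss = np.asarray(self.per_order_ss, dtype=float)


def walsh_forward(ls: Landscape) -> Spectrum:
    """Decompose a landscape into its Walsh interaction coefficients."""
    return Spectrum(L=ls.L, E=fwht(ls.W) / 2**ls.L)


def walsh_inverse(sp: Spectrum) -> Landscape:
    """Reconstruct the landscape whose coefficients are ``sp.E``."""
    return Landscape(L=sp.L, W=fwht(sp.E))


def fourier_spectrum(sp: Spectrum) -> FourierSpectrum:
    """Aggregate squared coefficients by epistatic order.

    For landscapes whose fitness values are i.i.d., every coefficient is
    i.i.d. as well, so the expected per-order sum is proportional to the
    binomial coefficient C(L, order).
    """
    ss = np.bincount(sp.orders, weights=sp.E**2, minlength=sp.L + 1)
    return FourierSpectrum(per_order_ss=ss)
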