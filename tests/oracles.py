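"""Independent brute-force reference implementations used across the tests.

These deliberately avoid the code paths they check: the Hadamard matrix is
built entry-by-entry from popcounts, tau-b counts all O(n^2) pairs, and the
best-m optimality check enumerates every coefficient subset.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def popcount_hadamard(L: int) -> np.ndarray:
    n = 2**L
    H = np.empty((n, n))
    for j in range(n):
        for k in range(n):
            H[j, k] = (-1) ** bin(j & k).count("1")
    return H


def brute_tau_b(x, y) -> float:
    x = np.asarray(x)
    y = np.asarray(y)
    P = Q = tx = ty = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[j] - x[i])
            dy = np.sign(y[j] - y[i])
            if dx and dy:
                if dx == dy:
                    P += 1
                else:
                    Q += 1
            elif dy:
                tx += 1
            elif dx:
                ty += 1
    return (P - Q) / math.sqrt((P + Q + tx) * (P + Q + ty))


def all_subset_residuals(E: np.ndarray, m: int) -> list[float]:
    """Residual sum of squared excluded coefficients for every m-subset."""
    n = len(E)
    total = float(np.sum(E**2))
    out = []
    for keep in itertools.combinations(range(n), m):
        kept = sum(E[k] ** 2 for k in keep)
        out.append(total - kept)
    return out
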