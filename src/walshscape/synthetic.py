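"""Synthetic landscapes with controlled epistatic structure and noise.

Two study conditions are emulated: coefficient magnitudes that *decay* with
interaction order (the declining-influence hypothesis; positive control) and
i.i.d. coefficients of every order (the maximally epistatic limit in which
genotype fitness values are i.i.d.; negative control).  Gaussian per-genotype
measurement noise with replicate averaging matches the normal-noise
assumption used when back-computing variances from confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import Landscape
from .transform import Spectrum, fwht, subset_orders

__all__ = ["SpectrumSpec", "decaying_spectrum", "landscape_from_spectrum"]


@dataclass
class SpectrumSpec:
    """Generator settings: per-order coefficient scales, noise and replication.

    ``order_scale[o]`` is the standard deviation of coefficients of order o.
    ``mean_offset`` pins the order-0 coefficient (mean fitness) to a constant,
    mirroring empirical landscapes where the mean dominates; set it to None to
    leave the order-0 coefficient as an i.i.d. draw (needed for the i.i.d.
    negative control, where no coefficient may be privileged).
    """

    L: int
    order_scale: list[float] | np.ndarray
    noise_sd: float = 0.0
    n_reps: int = 1
    seed: int = 0
    mean_offset: float | None = 1.0

    def __post_init__(self) -> None:
        self.order_scale = np.asarray(self.order_scale, dtype=float)
        if self.order_scale.shape != (self.L + 1,):
            raise ValueError("order_scale must have length L + 1")
        if np.any(self.order_scale < 0) or self.noise_sd < 0:
            raise ValueError("scales must be nonnegative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def decaying_spectrum(spec: SpectrumSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw coefficients E[k] ~ N(0, order_scale[order(k)]**2) independently."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    orders = subset_orders(spec.L)
    E = rng.normal(0.0, 1.0, size=2**spec.L) * spec.order_scale[orders]
    if spec.mean_offset is not None:
        E[0] = spec.mean_offset
    return E


def landscape_from_spectrum(
    E: np.ndarray,
    noise_sd: float = 0.0,
    n_reps: int = 1,
    seed: int = 0,
) -> Landscape:
    """Invert a coefficient vector and add replicated Gaussian measurement noise.

    Each genotype's reported fitness is the mean of ``n_reps`` draws from
    N(W_g, noise_sd**2) and its reported variance the sample variance of the
    draws (zero when ``noise_sd`` is 0; absent when a single replicate makes
    a sample variance undefined).
    """
    E = np.asarray(E, dtype=float)
    n = E.size
    if n == 0 or n & (n - 1):
        raise ValueError("coefficient vector length must be a power of two")
    L = n.bit_length() - 1
    W = fwht(E)
    if noise_sd == 0:
        return Landscape(L=L, W=W, var=np.zeros(n), nrep=np.full(n, n_reps),
                         meta={"noise_sd": 0.0, "seed": seed})
    rng = np.random.default_rng(seed)
    draws = rng.normal(W, noise_sd, size=(n_reps, n))
    Wbar = draws.mean(axis=0)
    var = draws.var(axis=0, ddof=1) if n_reps > 1 else None
    return Landscape(L=L, W=Wbar, var=var, nrep=np.full(n, n_reps),
                     meta={"noise_sd": noise_sd, "seed": seed})


def true_spectrum(E: np.ndarray) -> Spectrum:
    """Wrap a generated coefficient vector for comparison with recovered ones."""
    E = np.asarray(E, dtype=float)
    return Spectrum(L=E.size.bit_length() - 1, E=E)
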