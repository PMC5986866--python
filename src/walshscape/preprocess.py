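"""Fitness-scale transformations and experimental-variance bookkeeping.

Growth-rate and drug-resistance proxies are analysed on the natural-log
scale.  When only per-genotype means and variances are reported, the log
moments are approximated by first-order Taylor expansion:

    mean[ln x] ~= ln(xbar) - s^2 / (2 xbar^2)
    var[ln x]  ~= (s / xbar)^2

Zero fitness values have no logarithm and are replaced by a fill value
(default -2 on the natural-log scale, roughly one log order below typical
smallest nonzero log values in resistance assays).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .landscape import Landscape

__all__ = [
    "VarianceSummary",
    "approx_log_moments",
    "log_transform_landscape",
    "ci95_to_variance",
    "experimental_variance_fraction",
]

DEFAULT_ZERO_FILL = -2.0


def approx_log_moments(mean: float, var: float) -> tuple[float, float]:
    """Taylor-approximate (mean, variance) of ln(x) from moments of x.

    Reduces to ``(ln(mean), 0)`` as ``var -> 0``.
    """
    if mean <= 0:
        raise ValueError("mean must be positive to take a log")
    if var < 0:
        raise ValueError("variance must be nonnegative")
    log_mean = math.log(mean) - var / (2.0 * mean**2)
    log_var = (math.sqrt(var) / mean) ** 2
    return log_mean, log_var


def log_transform_landscape(
    ls: Landscape, zero_fill: float = DEFAULT_ZERO_FILL
) -> Landscape:
    """Natural-log transform of a landscape's fitness values.

    Positive fitness values are mapped by ``approx_log_moments`` when a
    per-genotype variance is present and by plain ``ln`` otherwise.  Zero
    fitness is replaced by ``zero_fill``; its log-scale variance is undefined
    and recorded as 0 with a warning.  Negative fitness is an error.
    """
    if np.any(ls.W < 0):
        raise ValueError("cannot log-transform negative fitness values")
    n = ls.n_genotypes
    W = np.empty(n)
    var = np.empty(n) if ls.var is not None else None
    zero_seen = False
    for g in range(n):
        if ls.W[g] == 0:
            W[g] = zero_fill
            if var is not None:
                var[g] = 0.0
                zero_seen = zero_seen or ls.var[g] > 0
        elif var is not None:
            W[g], var[g] = approx_log_moments(ls.W[g], ls.var[g])
        else:
            W[g] = math.log(ls.W[g])
    if zero_seen:
        warnings.warn(
            "zero fitness with nonzero variance: log-scale variance set to 0",
            stacklevel=2,
        )
    meta = dict(ls.meta, log_transform=True, zero_fill=zero_fill)
    return Landscape(L=ls.L, W=W, var=var, nrep=ls.nrep, labels=ls.labels, meta=meta)


def ci95_to_variance(ci95: float, n: int) -> float:
    """Back-compute a variance from a reported 95% confidence half-width.

    Implements ``(n * ci95 / 1.96)**2`` under a normal-noise assumption.

    .. warning::
       The conventional back-calculation from a CI on a mean of ``n``
       replicates would use ``sqrt(n)``, not ``n``.  The linear-``n`` form is
       kept deliberately to match the published bookkeeping; override upstream
       if your data require the conventional formula.
    """
    if ci95 <= 0:
        raise ValueError("ci95 must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    return (n * ci95 / 1.96) ** 2


@dataclass
class VarianceSummary:
    """Pooled experimental variance as a fraction of total landscape variance."""

    pooled_var: float
    model_var: float

    @property
    def exp_var_fraction(self) -> float:
        return self.pooled_var / self.model_var


def experimental_variance_fraction(ls: Landscape) -> VarianceSummary:
    """Pool per-genotype variances (unweighted mean) against landscape variance.

    ``model_var`` is the population variance of W (divide by ``2**L``),
    matching the Parseval bookkeeping of the Walsh decomposition.
    """
    if ls.var is None:
        raise ValueError("landscape carries no experimental variances")
    model_var = float(np.mean((ls.W - ls.W.mean()) ** 2))
    if model_var == 0:
        raise ValueError("constant landscape: variance fraction undefined")
    pooled = float(np.mean(ls.var))
    return VarianceSummary(pooled_var=pooled, model_var=model_var)
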