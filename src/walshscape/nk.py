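"""Kauffman NK landscapes and topography statistics.

Each of N loci contributes a fitness component drawn from U[0, 1) that
depends on its own allele and the alleles at K other loci chosen uniformly
at random; genotype fitness is the mean of the N contributions.  K tunes
ruggedness: K = 0 gives an additive, single-peaked landscape whose Walsh
coefficients of order >= 2 vanish; K = N - 1 makes genotype fitness values
i.i.d. and the landscape maximally rugged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .landscape import Landscape

__all__ = ["NKConfig", "generate_nk", "count_maxima"]


@dataclass
class NKConfig:
    """Reproducible description of one NK landscape draw."""

    N: int
    K: int
    seed: int
    neighborhoods: list[list[int]]
    tables: np.ndarray  # shape (N, 2**(K+1))

    def to_json(self) -> str:
        return json.dumps(
            {
                "N": self.N,
                "K": self.K,
                "seed": self.seed,
                "neighborhoods": self.neighborhoods,
                "tables": self.tables.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NKConfig":
        d = json.loads(text)
        return cls(
            N=d["N"],
            K=d["K"],
            seed=d["seed"],
            neighborhoods=[list(nb) for nb in d["neighborhoods"]],
            tables=np.asarray(d["tables"], dtype=float),
        )


def _nk_fitness(cfg: NKConfig) -> np.ndarray:
    n_geno = 2**cfg.N
    W = np.zeros(n_geno)
    for g in range(n_geno):
        total = 0.0
        for locus in range(cfg.N):
            key = (g >> locus) & 1
            for pos, nb in enumerate(cfg.neighborhoods[locus]):
                key |= ((g >> nb) & 1) << (pos + 1)
            total += cfg.tables[locus, key]
        W[g] = total / cfg.N
    return W


def generate_nk(N: int, K: int, seed: int) -> tuple[Landscape, NKConfig]:
    """Draw one NK landscape (neighborhoods and contribution tables seeded)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 <= K <= N - 1:
        raise ValueError(f"K must be in [0, {N - 1}]")
    rng = np.random.default_rng(seed)
    neighborhoods = []
    for locus in range(N):
        others = [l for l in range(N) if l != locus]
        nb = rng.choice(others, size=K, replace=False) if K else np.array([], int)
        neighborhoods.append(sorted(int(x) for x in nb))
    tables = rng.random((N, 2 ** (K + 1)))
    cfg = NKConfig(N=N, K=K, seed=seed, neighborhoods=neighborhoods, tables=tables)
    ls = Landscape(
        L=N, W=_nk_fitness(cfg), meta={"model": "NK", "N": N, "K": K, "seed": seed}
    )
    return ls, cfg


def landscape_from_config(cfg: NKConfig) -> Landscape:
    """Rebuild the landscape encoded by a serialized :class:`NKConfig`."""
    return Landscape(
        L=cfg.N,
        W=_nk_fitness(cfg),
        meta={"model": "NK", "N": cfg.N, "K": cfg.K, "seed": cfg.seed},
    )


def count_maxima(ls: Landscape) -> int:
    """Number of genotypes strictly fitter than all L single-mutant neighbors.

    A genotype tied with a neighbor is not counted as a maximum on either
    side; ties trigger a warning because real (rounded) data can contain
    them and silently double-counting peaks would corrupt topography tables.
    """
    L, W = ls.L, ls.W
    count = 0
    tie_seen = False
    for g in range(2**L):
        neighbors = W[[g ^ (1 << b) for b in range(L)]]
        if np.any(neighbors == W[g]):
            tie_seen = True
        if np.all(W[g] > neighbors):
            count += 1
    if tie_seen:
        warnings.warn("fitness ties between neighbors; tied genotypes not counted",
                      stacklevel=2)
    return count
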