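"""Data model and I/O for combinatorially complete fitness landscapes.

A landscape over ``L`` biallelic loci assigns one fitness value (or a fitness
proxy such as a growth rate, MIC or IC50) to each of the ``2**L`` genotypes.
Genotypes are written as L-character 0/1 strings and stored in *canonical
order*: ascending L-bit binary numbers, where the **leftmost character of the
genotype string is the most significant bit** (locus 1).  Index 0 is the
all-zeros reference genotype.  Every statistic downstream is invariant to
locus permutation, so the bit convention only matters when comparing
individual interaction coefficients across implementations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Landscape",
    "canonical_index",
    "read_landscape",
    "write_landscape",
    "slice_biallelic",
]


def canonical_index(bits: str) -> int:
    """Map an L-character 0/1 genotype string to its canonical integer index.

    The leftmost character is the highest-order bit, so ``"101" -> 5``.

    Raises
    ------
    ValueError
        If the string is empty or contains characters other than 0/1.
    """
    if not bits or any(c not in "01" for c in bits):
        raise ValueError(f"genotype string must be nonempty 0/1, got {bits!r}")
    return int(bits, 2)


def _bitstring(index: int, L: int) -> str:
    return format(index, f"0{L}b")


@dataclass
class Landscape:
    """A combinatorially complete fitness landscape over L biallelic loci.

    Parameters
    ----------
    L : int
        Number of loci (>= 1).
    W : ndarray, shape (2**L,)
        Fitness values in canonical genotype order.
    var : ndarray or None
        Optional per-genotype experimental variances (>= 0).
    nrep : ndarray or None
        Optional per-genotype replicate counts (>= 1).
    labels : list of str or None
        Optional locus names, most significant bit first.
    meta : dict
        Free-form provenance.
    """

    L: int
    W: np.ndarray
    var: np.ndarray | None = None
    nrep: np.ndarray | None = None
    labels: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        self.W = np.asarray(self.W, dtype=float)
        n = 2**self.L
        if self.W.shape != (n,):
            raise ValueError(f"W must have length 2**L = {n}, got {self.W.shape}")
        if self.var is not None:
            self.var = np.asarray(self.var, dtype=float)
            if self.var.shape != (n,):
                raise ValueError("var must match W in length")
            if np.any(self.var < 0):
                raise ValueError("variances must be nonnegative")
        if self.nrep is not None:
            self.nrep = np.asarray(self.nrep, dtype=int)
            if self.nrep.shape != (n,):
                raise ValueError("nrep must match W in length")
            if np.any(self.nrep < 1):
                raise ValueError("replicate counts must be positive")
        if self.labels is not None and len(self.labels) != self.L:
            raise ValueError("labels must name all L loci")

    @property
    def n_genotypes(self) -> int:
        return 2**self.L

    def genotypes(self) -> list[str]:
        """All genotype bitstrings in canonical order."""
        return [_bitstring(i, self.L) for i in range(2**self.L)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"genotype": self.genotypes(), "fitness": self.W})
        if self.var is not None:
            df["variance"] = self.var
        if self.nrep is not None:
            df["n"] = self.nrep
        return df


def read_landscape(
    path,
    *,
    sep: str | None = None,
    genotype_col: str = "genotype",
    fitness_col: str = "fitness",
    variance_col: str | None = "variance",
    nrep_col: str | None = "n",
) -> Landscape:
    """Read a delimited landscape table and put it in canonical order.

    The file must have a header, a genotype column of L-character 0/1 strings
    and a fitness column; variance and replicate columns are picked up when
    present.  Rows may appear in any order; each genotype must appear exactly
    once and all ``2**L`` genotypes must be present.

    ``sep=None`` sniffs comma/tab delimiters.
    """
    df = pd.read_csv(
        path,
        sep=sep,
        engine="python" if sep is None else "c",
        dtype={genotype_col: str},  # keep leading zeros
    )
    for col in (genotype_col, fitness_col):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    return landscape_from_table(
        df,
        genotype_col=genotype_col,
        fitness_col=fitness_col,
        variance_col=variance_col if variance_col in df.columns else None,
        nrep_col=nrep_col if nrep_col in df.columns else None,
    )


def landscape_from_table(
    df: pd.DataFrame,
    *,
    genotype_col: str = "genotype",
    fitness_col: str = "fitness",
    variance_col: str | None = None,
    nrep_col: str | None = None,
    meta: dict | None = None,
) -> Landscape:
    """Build a :class:`Landscape` from an in-memory genotype/fitness table."""
    geno = df[genotype_col].astype(str).tolist()
    lengths = {len(g) for g in geno}
    if len(lengths) != 1:
        raise ValueError(f"ragged genotype strings: lengths {sorted(lengths)}")
    L = lengths.pop()
    if L < 1:
        raise ValueError("empty genotype strings")
    idx = [canonical_index(g) for g in geno]
    counts = np.bincount(idx, minlength=2**L)
    dup = [_bitstring(i, L) for i in np.nonzero(counts > 1)[0]]
    if dup:
        raise ValueError(f"duplicate genotypes: {', '.join(dup)}")
    missing = [_bitstring(i, L) for i in np.nonzero(counts == 0)[0]]
    if missing:
        raise ValueError(
            f"incomplete landscape, missing genotypes: {', '.join(missing)}"
        )
    order = np.argsort(idx, kind="stable")
    W = df[fitness_col].to_numpy(dtype=float)[order]
    var = df[variance_col].to_numpy(dtype=float)[order] if variance_col else None
    nrep = df[nrep_col].to_numpy()[order] if nrep_col else None
    return Landscape(L=L, W=W, var=var, nrep=nrep, meta=meta or {})


def write_landscape(ls: Landscape, path, *, sep: str = ",") -> None:
    """Write a landscape as delimited text (columns genotype, fitness[, variance, n])."""
    ls.to_dataframe().to_csv(path, sep=sep, index=False)


def slice_biallelic(
    df: pd.DataFrame,
    seed: int,
    *,
    genotype_col: str = "genotype",
    fitness_col: str = "fitness",
    variance_col: str | None = None,
    nrep_col: str | None = None,
) -> Landscape:
    """Take one biallelic slice through a landscape with multiallelic loci.

    Genotypes are strings of arbitrary allele characters, one per locus.  At
    every locus with more than two observed alleles, two alleles are chosen
    uniformly at random (seeded); rows are restricted to the chosen allele
    combinations.  At each locus the lexicographically smaller retained allele
    becomes "0".  The chosen alleles are recorded in ``meta["slice_alleles"]``.

    Raises
    ------
    ValueError
        If the resulting slice is not combinatorially complete (the caller
        decides whether to redraw with a different seed).
    """
    geno = df[genotype_col].astype(str).tolist()
    lengths = {len(g) for g in geno}
    if len(lengths) != 1:
        raise ValueError(f"ragged genotype strings: lengths {sorted(lengths)}")
    L = lengths.pop()
    rng = np.random.default_rng(seed)
    kept: list[tuple[str, str]] = []
    for pos in range(L):
        alleles = sorted({g[pos] for g in geno})
        if len(alleles) < 2:
            raise ValueError(f"locus {pos} has fewer than 2 alleles")
        if len(alleles) == 2:
            pair = alleles
        else:
            pair = sorted(rng.choice(alleles, size=2, replace=False))
        kept.append((pair[0], pair[1]))

    rows = []
    for i, g in enumerate(geno):
        bits = []
        ok = True
        for pos, c in enumerate(g):
            lo, hi = kept[pos]
            if c == lo:
                bits.append("0")
            elif c == hi:
                bits.append("1")
            else:
                ok = False
                break
        if ok:
            rows.append((i, "".join(bits)))
    sub = df.iloc[[i for i, _ in rows]].copy()
    sub[genotype_col] = [b for _, b in rows]
    try:
        ls = landscape_from_table(
            sub,
            genotype_col=genotype_col,
            fitness_col=fitness_col,
            variance_col=variance_col,
            nrep_col=nrep_col,
            meta={"slice_alleles": kept, "slice_seed": seed},
        )
    except ValueError as err:
        raise ValueError(f"biallelic slice is incomplete: {err}") from err
    return ls


def enumerate_biallelic_slices(alleles_per_locus: list[list[str]]):
    """Yield every possible biallelic allele choice (one pair per locus).

    Exhaustive-enumeration helper used to validate the seeded slicer on small
    tables.
    """
    pairs_per_locus = [
        [tuple(sorted(p)) for p in itertools.combinations(sorted(a), 2)]
        for a in alleles_per_locus
    ]
    yield from itertools.product(*pairs_per_locus)
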