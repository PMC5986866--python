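"""Reference results from a published survey of 16 empirical landscapes.

Uncorrected permutation-test P values (n = 1e5 replicates) reported for 16
published combinatorially complete fitness landscapes, used as inputs for the
cross-study uniformity diagnostic.  Entries reported only as an upper bound
"< 0.00001" are stored as 0.0 and fall in the lowest log-decade bin of
:func:`walshscape.stats.g_test_uniformity`.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["EMPIRICAL_STUDIES", "empirical_p_values"]

# (phenotype, L, tau_b, p_uncorrected; 0.0 encodes "< 0.00001")
EMPIRICAL_STUDIES = [
    ("log S. cerevisiae HSP90 mutant growth rate", 6, 0.6202, 0.0),
    ("log diploid S. cerevisiae mutant growth rate", 6, 0.6667, 0.0),
    ("log E. coli IMDH mutant relative growth rate", 6, 0.7566, 0.0),
    ("avian lysozyme thermostability", 3, 0.5, 0.0),
    ("log Methylobacterium extorquens relative fitness", 4, 0.7527, 0.00001),
    ("log HIV replicative capacity on CCR5+ cells", 5, 0.5703, 0.00002),
    ("log cefotaxime MIC of E. coli TEM alleles", 5, 0.5490, 0.00011),
    ("log fruit fly relative viability", 5, 0.4896, 0.00027),
    ("log cefalexin MIC of B. cereus metallo-beta-lactamase", 4, 0.5376, 0.00448),
    ("log LTEE E. coli relative fitness (DM25 + EGTA)", 5, 0.3486, 0.01023),
    ("log Aspergillus niger colony growth rate", 5, 0.4387, 0.02002),
    ("sesquiterpene synthase epi-aristolochene production", 6, 0.1974, 0.02639),
    ("log pyrimethamine IC50 of P. falciparum DHFR alleles", 4, 0.4337, 0.03133),
    ("log trimethoprim IC75 of E. coli DHFR alleles", 6, 0.1921, 0.03639),
    ("mammalian glucocorticoid receptor cortisol sensitivity", 4, 0.1075, 0.30182),
    ("log ampicillin MIC of E. coli TEM alleles", 4, 0.0430, 0.41356),
]


def empirical_p_values() -> list[float]:
    """The 16 uncorrected P values (0.0 where only "< 0.00001" was reported)."""
    return [row[3] for row in EMPIRICAL_STUDIES]


def empirical_table() -> pd.DataFrame:
    return pd.DataFrame(
        EMPIRICAL_STUDIES, columns=["phenotype", "L", "tau_b", "p_uncorrected"]
    )
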