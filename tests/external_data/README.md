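# Optional empirical inputs

The per-dataset integration tests run only when the corresponding archived
empirical landscape is placed here; nothing is bundled with the package.

Expected file: `trimethoprim_ic75.csv` — the combinatorially complete
6-locus trimethoprim-IC75 landscape of E. coli DHFR alleles, converted to
the package's delimited format:

    genotype,fitness,variance,n
    000000,<IC75>,<variance>,<replicates>
    ...

with fitness on the raw (pre-log) scale; the test applies the natural-log
transform and variance truncation itself.
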