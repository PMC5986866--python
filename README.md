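# walshscape

Tools for asking how much **higher-order epistasis** shapes the topography of
biological fitness landscapes.

A combinatorially complete dataset measures a fitness proxy (growth rate,
MIC, IC50/IC75, replicative capacity, thermostability...) for all `2^L`
genotypes over `L` biallelic loci.  Any such landscape `W` is equivalent to a
full suite of interaction coefficients via the Fourier–Walsh transform

```
E = (1 / 2^L) Ψ W,          W = Ψ E,          Ψ[j,k] = (−1)^popcount(j & k)
```

where `Ψ` is the Sylvester Hadamard matrix (`Ψ² = 2^L I`).  The coefficient
at subset index `k` is the background-averaged interaction among the loci in
`k`; its *epistatic order* is `popcount(k)` (order 0 = mean, order 1 = main
effects, order ≥ 2 = epistasis proper).

Because the transform is orthogonal, keeping the `m` largest-magnitude
coefficients and zeroing the rest yields — for every `m` — the `m`-parameter
model with minimal residual sum of squares.  If epistatic influence declines
with order, the orders of the magnitude-ranked coefficients should resemble
the combinatoric expectation

```
0, 1 ×L, 2 ×C(L,2), ..., L        (one k for every k-subset of loci)
```

`walshscape` measures that resemblance with Kendall's τ_b (ties corrected on
both sides), attaches a one-tailed permutation P value (null: τ_b between two
random permutations of the expectation multiset), truncates noisy terms when
experimental variances are reported (terms are discarded once the remaining
model variance falls below the pooled experimental variance), applies the
Holm correction across studies, and summarises a study collection with a
G-test of P-value uniformity.  Tunably rugged NK landscapes and synthetic
spectra with controlled per-order coefficient scales are built in, so every
stage can be exercised without external data.

## Worked example

```python
from walshscape import (SpectrumSpec, decaying_spectrum, landscape_from_spectrum,
                        LandscapeStudy)

# a 4-locus landscape whose coefficient scale halves with each order,
# measured with Gaussian noise (sd 0.05) in 6 replicates per genotype
spec = SpectrumSpec(L=4, order_scale=[0.0, 0.5, 0.25, 0.125, 0.0625],
                    noise_sd=0.05, n_reps=6, seed=11)
ls = landscape_from_spectrum(decaying_spectrum(spec), spec.noise_sd,
                             spec.n_reps, spec.seed)
res = LandscapeStudy(ls, n_reps=100_000, seed=0,
                     name="synthetic decaying L=4").fit()
print(res.summary())
```

```
Landscape study: synthetic decaying L=4
==============================================
loci (L)                    4
genotypes                   16
local maxima                3
log transform               False
experimental var fraction   0.0015
retained terms (m*)         12
discarded terms (j)         4
Kendall tau_b               0.5556
P (one-tailed, 100000 reps)  0.02642
----------------------------------------------
reduction in residual variance by order:
 order  aggregate_reduction  n_terms  mean_reduction
     0               0.0000        1          0.0000
     1               0.6889        4          0.1722
     2               0.3082        6          0.0514
     3               0.0017        1          0.0017
```

Reading the output: replicate noise puts the pooled experimental variance at
0.15% of the landscape variance, so the 4 weakest of the 16 ranked terms are
discarded (`m* = 12`).  The retained order sequence correlates positively
with the combinatoric expectation (τ_b = 0.556) and only ~2.6% of random
permutation pairs do as well or better — the declining-influence structure
that the generator planted is detected.  First-order terms explain 69% of
the variance about the mean, pairwise terms 31%, and the per-term influence
(`mean_reduction`) falls monotonically with order.

The same analysis runs from the shell:

```
walshscape simulate-nk -n 5 -k 2 --seed 1 -o nk.csv
walshscape study nk.csv --reps 100000 --seed 1
walshscape study-set a.csv b.csv c.csv --reps 100000
```

`LandscapeStudy.from_file` reads any delimited table with `genotype`
(L-character 0/1 string, leftmost character = most significant bit) and
`fitness` columns, plus optional `variance` and `n` columns; multiallelic
tables can be reduced with `slice_biallelic`.

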