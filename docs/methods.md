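# Methods

## Model and decomposition

A combinatorially complete landscape over `L` biallelic loci is a vector `W`
of `2^L` fitness values in canonical order (ascending binary genotype,
leftmost string character = most significant bit; index 0 is the reference
genotype).  The Fourier–Walsh transform `E = Ψ W / 2^L` with the Sylvester
Hadamard matrix `Ψ[j,k] = (−1)^popcount(j∧k)` maps it to `2^L` interaction
coefficients, one per subset of loci; the inverse is `W = Ψ E`.  The
implementation uses the O(n log n) butterfly transform; the explicit matrix
product (built entry-wise from popcounts) is retained as the test oracle and
the two agree to 1e−12 on all tested sizes.

Sign conventions: which allele is "0" fixes the signs of individual
coefficients but not their magnitudes or orders, and every downstream
statistic uses magnitudes and orders only.  Coefficient-level comparisons
with other software additionally require the same locus ordering.

Bookkeeping is in the population (divide by `2^L`) convention throughout, so
Parseval gives: mean squared deviation of `W` about its mean = Σ_{k≠0} E_k².
The residual-variance fraction of the best-`m` model is therefore the sum of
squared *excluded* non-zero-index coefficients over Σ_{k≠0} E_k²; the
order-0 term, while usually the largest magnitude and ranked first, explains
none of the variance about the mean.

## Ranking, ties, and exact zeros

Terms are ranked by descending |E| with ties broken by ascending canonical
subset index (a stable, deterministic rule).  Coefficients whose magnitude is
below `1e−12 × max|E|` are snapped to zero before ranking.  This matters for
structurally additive landscapes: their order ≥ 2 coefficients are exactly
zero analytically but carry ~1e−17 arithmetic noise, and without the snap the
tie order among them — hence the ranked-order sequence and τ_b — would be an
irreproducible artifact of round-off.  With it, the additive NK control below
is bit-reproducible across seeds.  The snap threshold is relative, far below
any resolvable coefficient, and does not affect landscapes without exact
structural zeros.

## Preprocessing

Growth-rate and resistance proxies are analysed on the natural-log scale.
Zero fitness maps to a fill value (default −2, roughly one log order below
typical smallest nonzero log values; overridable).  When only means and
variances are reported, log moments use the first-order Taylor rules
`ln(x̄) − s²/(2x̄²)` and `(s/x̄)²`; a zero-fitness genotype has no defined
log-scale variance and is recorded as 0 with a warning.  A reported 95% CI
half-width is converted as `(n·CI95/1.96)²`; note the linear-`n` factor is
kept deliberately for compatibility with the published bookkeeping even
though the conventional back-calculation would use `√n`.

Per-genotype variances are pooled by unweighted mean (the choice among
mean/median/sum is not dictated by anything upstream; the unweighted mean is
the least structured) and divided by the population variance of `W` to give
the experimental-variance fraction.  The ranked sequence is truncated at the
smallest `m` whose residual fraction falls below that threshold — the
cumulative ("remaining model variance < experimental variance") rule.  An
element-wise alternative ("drop every term whose own reduction is below the
threshold") would discard more terms whenever many individually
sub-threshold terms jointly exceed the threshold; the cumulative rule is the
implemented and documented behavior.
The `j = 2^L − m*` discarded orders are also dropped from the tail of the
expectation vector.

## Test statistic and null

τ_b between the retained ranked orders and the equal-length prefix of the
expectation multiset {0, 1×L, ..., L} uses the standard tie-corrected
formula (scipy's implementation, cross-checked against an O(n²) pair
counter).  The permutation null draws τ_b between two independent uniformly
random permutations of the expectation prefix — both sides permuted, which
matters when the observed multiset differs from the expectation's after
truncation.  Since both null vectors share one multiset, the tie-corrected
denominator is a constant and only the concordance count varies; the sampler
exploits this with vectorised pairwise sign products (~1e5 draws/s at
n = 32).  P is the fraction of null draws ≥ the empirical value (one-tailed;
a float tolerance of 1e−12 guards the ≥ comparison); when no draw qualifies
P is recorded as 0 and displayed as "< 1/n_reps".  Exhaustive enumeration
over all distinct permutation pairs replaces sampling on request (feasible
for very short vectors; for [0,1,1,2] it gives P(τ=1) = 12/144 = 1/12
exactly).  Default replicates: 1e5.  All randomness flows through one named
generator per study; the seed is recorded in the result.

Across a study set, Holm's step-down correction controls the family-wise
error rate (stars: *** ≤ 0.001, ** ≤ 0.01, * ≤ 0.05 on corrected values,
reported beside uncorrected P).  The joint skew of uncorrected P values is
summarised by a G-test against uniformity on log-decade bins
(0, 1e−5], (1e−5, 1e−4], ..., (0.1, 1], with the lowest bin closed so that
"< bound" entries (stored as 0) are counted; df = bins − 1, referred to
χ².  Bin edges are configurable; G moves by a few percent under reasonable
alternative binnings of values reported only as bounds.

## Simulators

**NK.**  N loci; each locus's U[0,1) contribution table depends on its own
state and K others drawn uniformly at random without replacement; genotype
fitness is the mean of the N contributions (mean vs. sum is immaterial for
every rank statistic here; the mean keeps fitness in [0,1) with the order-0
coefficient ≈ 0.5 dominant).  K = 0 is additive and single-peaked; K = N−1
makes genotype fitness i.i.d.  Landscape topography is summarised by the
number of local maxima (strictly fitter than all L Hamming-1 neighbors;
ties warn and count for neither side).

**Synthetic spectra.**  Coefficients are drawn independently,
`E_k ~ N(0, order_scale[order(k)]²)`; the order-0 coefficient is pinned to a
constant offset (default 1) to mirror empirical landscapes where mean
fitness dominates, or left random (`mean_offset=None`) when no coefficient
may be privileged.  Measurement error is i.i.d. Gaussian per genotype,
averaged over `n_reps` replicates, with the sample variance reported —
matching the normal-noise assumption of the CI conversion.  Error
propagation through the orthogonal transform gives recovered-coefficient
errors of sd `noise_sd / sqrt(n_reps · 2^L)`, verified by simulation.

What the generators do *not* emulate: fitness-scale nonlinearity (no
monotone rescaling is fitted), correlated or heteroskedastic measurement
error, and missing genotypes.  Green synthetic tests therefore demonstrate
the statistics' calibration and power under clean Gaussian conditions, not
robustness to those real-data complications.

## Expected behavior of the controls

*Additive NK control (N=5, K=0).*  The ranked sequence is the order-0 term,
the five order-1 terms, then the 26 exact zeros in canonical order, giving
τ_b = 284/386 ≈ 0.7358 deterministically, with permutation P below 1e−5 at
1e5 replicates.  Note that any procedure that instead lets round-off noise
order the zero coefficients turns this statistic into a random draw
(mean 161/386 ≈ 0.417, sd ≈ 0.10 under a uniformly random tie order), which
is why the deterministic tie policy above is load-bearing.

*i.i.d. limit.*  For i.i.d. *coefficients* (constant `order_scale`, no
pinned mean) E[τ_b] = 0 by symmetry.  For i.i.d. *fitness* (K = N−1 NK) the
dominant order-0 coefficient still ranks first, fixing 31 always-concordant
pairs and flooring the expected τ_b at 31/386 ≈ 0.080; simulated means run
slightly above the floor (~0.10) because non-Gaussian fitness leaves weak
dependence among magnitudes of XOR-linked coefficient triples.  "≈ 0" for
this limit is therefore accurate only at the scale of the per-study null sd
(≈ 0.15), and the tests assert exactly that.

*Power.*  With coefficient scales halving per order at L = 4, the one-tailed
test at α = 0.05 detects the decline in ≥ 90 of 100 seeded runs at 2000
permutations.

## Problem sizes and numerics

Exhaustive optimality checks enumerate all coefficient subsets at L = 2, 3
(20 random landscapes each); transform identities are asserted through
L = 6; null-calibration uses 500 simulated studies at 2000 permutations and
power curves 100–200 runs — sizes chosen so the whole suite completes in
seconds while keeping Monte-Carlo error well inside the asserted margins.
Degenerate inputs (constant landscapes, constant rank vectors, empty P-value
sets) raise rather than return NaN; thresholds ≥ total variance truncate to
zero retained terms with a warning.
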