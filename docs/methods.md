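# Methods

## Code space and encoding

The package works in the restrictive encoding throughout. The canonical
code's 20 synonymous-codon blocks (taken from the standard codon table,
NCBI table 1, via Biopython) and the three stop codons UAA/UAG/UGA are
fixed; a genetic code is a permutation of the 20 standard amino acids over
the blocks. Blocks are indexed by their lexicographically smallest codon
(U < C < A < G), and every serialized output labels blocks explicitly, so
the internal ordering carries no meaning. Codons are RNA internally; DNA
input is normalized (T → U) on read. Nonrestrictive codes (arbitrary
61-codon maps) are out of scope.

## Scoring

`Ms` is the mean squared difference of an amino-acid property over the
unordered pairs of sense codons that differ at exactly one base. With the
canonical block structure there are 263 such pairs: 288 single-base pairs
among all 64 codons minus the 25 involving a stop codon. Pairs involving a
stop are excluded entirely — they contribute to neither numerator nor
denominator. `Mst` replaces the plain mean with a weighted mean; the
weight of a pair depends on the substituted base position and on whether
the base change is a transition (A↔G, C↔U) or a transversion, with
defaults (1, 0.5, 1) / (0.5, 0.1, 1) for bases 1–3. The normalizer is the
sum of weights over all 263 pairs (166.8 with the default scheme), so
uniform weights collapse `Mst` to `Ms` exactly. These conventions — stop
exclusion, unordered pairs, weighted-mean normalizer — are pinned down
jointly by the six canonical reference values (5.19 / 9.39 / 2266.13 for
Ms and 2.63 / 4.6 / 1766.77 for Mst under PR / HI / MV), which the
implementation reproduces to printed precision.

Evaluation is algebraically regrouped by blocks: substitution pairs are
aggregated once into a symmetric 20×20 matrix `M` of inter-block weight
totals (intra-block pairs add weight only to the normalizer; their
property difference is zero), after which

    score(C) = (x'diag(M·1)x − x'Mx) / normalizer,   x = property ∘ C

costs O(20²) per code and vectorizes over batches of codes. The block
evaluator is verified against direct codon-level enumeration to 1e-9
relative in the test suite. Because the identity subtracts two nearly
equal quantities, a constant property vector yields ~1e-15 rather than an
exact 0; tests treat anything below 1e-12 as zero.

Built-in property scales are polar requirement, the Kyte–Doolittle
hydropathy index, and Grantham molecular volume (Gly = 3 on that scale,
used verbatim). Custom scales load from a two-column CSV.

## NSGA-II

The optimizer is the standard elitist NSGA-II specialized to permutation
individuals:

* random initial population of uniform permutations;
* fast nondominated sorting into layers, crowding distance within layers;
* offspring by tournament selection under the crowded comparison (lower
  rank, then larger crowding, then a uniform random tie-break) followed by
  swap mutation — two distinct blocks chosen uniformly, amino acids
  exchanged — applied at most once per offspring with probability
  `swap_probability`; no crossover;
* μ+λ environmental selection: whole layers of parents+offspring are
  taken in rank order and the last layer is truncated by crowding distance
  (ties broken by objective-lexicographic order, then index, for exact
  reproducibility). Elitism is subsumed by this truncation; the per-
  objective best is asserted non-worsening every generation.

Defaults mirror the reference experiment: population 100, 1000
generations, swap probability 0.5, tournament pool 3% of the population
(rounded, minimum 2 — a pool of 1 would be no selection), 10 independent
runs whose nondominated sets are merged (union, duplicate assignments
dropped, nondominated filtering). Each run draws every random number from
one generator seeded by a sub-seed spawned deterministically from the
master seed, so fronts are bit-reproducible. Internally a population is an
(M, 20) integer array and sorting/selection/mutation are vectorized; a
full-scale run takes a few seconds, so tests exercise paper-scale settings
directly (with 3 runs rather than 10 where several runs suffice).

Whether mutation may hit the same individual twice per generation is not
prescribed by the experimental description; a single application per
offspring was chosen as the plainest reading of "a 50% chance of suffering
swap".

## Random-code statistics

`sample_summary` draws uniform random permutations, evaluates all
objectives in vectorized batches, and accumulates mean, sample standard
deviation, min/max, the count of codes strictly better (strictly lower)
than canonical, and a histogram in one streaming pass, so memory is
independent of n. Histogram edges are fixed from the first batch's range
widened by half a range on each side; later values outside that span are
clipped into the end bins, so counts always sum to n (with 10⁵+ samples
per batch the clipped fraction is negligible). Bins default to 50.

For the restrictive space the mean evaluation over all 20! codes also has
a closed form: under a uniform permutation any two distinct blocks carry
an exchangeable pair of distinct amino acids, so every inter-block pair
contributes E[(X_i − X_j)²] = Σ_{i≠j}(x_i − x_j)²/(20·19) and

    E[score] = (inter-block weight / normalizer) × Σ_{i≠j}(x_i − x_j)²/380.

This gives E[Ms] = 9.4099 / 13.2982 / 2749.90 and E[Mst] = 7.6304 /
10.7834 / 2229.88 for PR / HI / MV, and serves as an independent check on
the Monte-Carlo estimates (they agree within CLT error in the tests).

`pmd` follows the definition above and is undefined (signalled as
`ZeroDivisionError`, or a flagged row in tables) when a code's evaluation
equals the random mean. In comparison tables pmd is reported only for
members that dominate the canonical code, since otherwise the ratio
exceeds 100% and loses its interpretation. The normalization behind the
Euclidean distance column is configurable (divide-by-random-mean default,
z-score and min-max alternatives); no documented choice reproduces the
historically printed distance values, so the distance is reported but not
treated as a reference quantity.

## Scope of the synthetic null and known limitations

The random-code null is the uniform distribution over restrictive
permutations — the same space the optimizer searches. Two published
reference quantities are *not* reproduced under this null and are left as
known discrepancies rather than fitted:

* The published best-pmd values imply random-code means (≈9.32 for Ms·PR,
  ≈13.15 for Ms·HI, ≈10.53 for Mst·HI, recovered consistently by
  inverting the pmd formula on independent table rows) that sit several
  hundred Monte-Carlo standard errors away from the exact restrictive
  expectation. Recomputed pmd values therefore land within about 0.2–0.9
  percentage points of the published ones (93.74 vs 93.731 for Mst·PR, but
  86.96 vs 86.793 for Ms·PR), not within printed precision.
* The published counts of random codes better than canonical (0 / 97 /
  466 per 10⁷ for Ms under PR / HI / MV; 0 / 0 / 20 for Mst) are orders of
  magnitude below what uniform restrictive sampling yields (at 10⁶:
  143 / 7798 / 108705 and 3 / 77 / 102738 with seed 1). The uniform-
  permutation counts do match the classic statistical-approach literature
  (roughly 1–2×10⁻⁴ of block-permutation codes beat the canonical code on
  squared polar requirement, and about one in a million under
  mistranslation weighting), so the discrepancy is attributed to an
  unstated difference in the published random-code generator, not to the
  scoring. The corresponding reproduction tests assert the published
  values at their stated tolerances and fail; they are retained as an
  honest record.

Other limitations: the search and the null cover only restrictive codes,
so conclusions about the full space of 61-codon maps are out of reach;
objective counts above ~3 would need many-objective machinery (reference
points) that is deliberately not included; and the gray-scale comparison
tables are emitted as TSV — shading/rendering is left to downstream tools.

## Problem sizes used in the checks

Deterministic scores use the full 263-pair enumeration. Monte-Carlo means
and tail counts use 10⁶ draws (standard error of the mean ≈ 0.0015 for
Ms·PR, perturbing pmd by well under 0.05 points). GA reproduction checks
run 3 independent paper-scale runs (population 100, 1000 generations).
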