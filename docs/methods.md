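# Methods

This note documents the models, conventions and numerical choices behind
`ovamir`, and what the synthetic-data generator does and does not emulate.

## Pipeline model

The pipeline reproduces the two-pooled-library design of era small-RNA
digital expression studies: one sequencing library per condition, no
biological replication at the sequencing level. All downstream statistics
inherit that design — in particular the exact test treats each library as a
Poisson sample of a fixed transcript pool, which is exactly the assumption
that pooling biological material strains (see *Known limitations*).

### Preprocessing

Filter chain, in fixed order: mean-Phred quality floor (default 20; the
definition of "low quality" is a convention, exposed as a flag) → 3′ adapter
trim at the leftmost exact prefix match with ≥ 6 nt overlap → insert length
selection to the 18–30 nt analysis window → collapse to unique tags → drop
tags seen once ("single-read sequences"). The order is pinned because it
decides which reject bucket a read lands in; the conservation identity
`raw = clean + Σ rejects` is asserted on every run. Reads with no
recognizable adapter are rejected by default (the insert cannot be
delimited); `keep_unmatched_adapter` retains them full-length instead.

### Annotation

Classification is exact matching with a fixed priority: miRNA (equality with
a mature or star sequence, or a hairpin substring confined to an annotated
arm) → rRNA/tRNA/snRNA/scRNA/snoRNA (any 18–30 nt window of a class
sequence) → genome (any substring) → unmatched. The original procedure maps
to the genome first, discards ncRNA classes, then keeps only perfect miRNA
matches; for perfect matches the final assignment is the same, and the
priority form makes "category totals partition the clean reads" an exact,
testable invariant. Ties among miRNA identifiers go to the lexicographically
smallest with a warning; identical mature sequences from several loci are
counted once under one identifier. Reported percentages round half-up to two
decimals, matching the printed convention of the source tables.

### Differential expression

NE = 10⁶·count/total; zero counts are imputed to NE = 0.01 for ratio
computation only; rows with NE < 1 in both libraries are removed; the
Audic–Claverie two-sided P-value is computed on raw counts via the
negative-binomial tail identity (the conditional law of `y` given `x` is
NB(x+1, N_a/(N_a+N_b))); calls use |log₂ ratio| ≥ 1 and P ≤ 0.05, both
inclusive. The test on raw counts rather than NE is a deliberate choice: the
test is only defined for counts, and imputation exists solely to keep ratios
finite.

Two properties of this construction worth knowing:

- **Imputation artifacts.** A presence/absence contrast (0 vs. a modest
  count) produces an arbitrarily large fold-change, bounded only by the
  imputation constant. This is faithful to the method; fold-change rankings
  should be read with the raw counts alongside.
- **Asymmetry of the two-sided P-value.** Doubling the smaller conditional
  tail is not exactly symmetric under swapping (x, N_a) ↔ (y, N_b). Near the
  null the two orientations converge as counts grow (≈1.5 % relative at
  counts ~10⁴), but deep in the tails a relative gap of order 10 % persists.
  The orientation is therefore fixed by the control-library argument, and
  the symmetry test asserts only the near-null convergence.

No multiple-testing correction is applied to calls (fidelity to the original
procedure); a BH-FDR column is emitted alongside for modern eyes.

## Synthetic data generator

The generator is the package's test bed: it draws a reference bundle
(mature/star/hairpin/genome/ncRNA), per-miRNA abundances, a designated DE
subset, counts, reads and qPCR Ct tables, all as pure functions of
(config, seed).

Default study conditions, chosen to emulate the ovary-library structure:

| parameter | default | rationale |
|---|---|---|
| `n_mirnas` | 300 | order of the known miRNA complement observed per library |
| `abundance_sigma_log` | 2.5 | log-normal spread reproducing per-miRNA reads from <20 to >10⁶ at realistic library sizes |
| `mirna_fraction` | 0.35 | miRNA-similar share of clean reads in the published libraries (27–40 %) |
| contamination | rRNA .12, tRNA .08, snRNA .02, scRNA .01, snoRNA .04, unannotated .38 | yields ≈70 % genome-mapped reads, matching the published 66–75 % range |
| `de_fraction` | 0.10 | a minority of miRNAs truly changed |
| `effect_min` | 1.0 | planted effects callable at the |log₂ ratio| ≥ 1 threshold |
| `star_ratio_log_mean` | log 0.03 | mature ≫ star arm ratios |
| `arm_inversion_prob` | 0.02 | occasional star-dominant duplexes (2–15× inverted ratio, the miR-140-like pattern) |
| length law | mode 22 > 23 > 21 nt | Dicer-product size profile |
| `dispersion` (NB φ) | 0.01 | mild overdispersion from pooling; φ = 0 gives the Poisson counts the exact test assumes |
| `library_sizes` | 10⁶ each | inside the simulated-library range; large enough for the power properties tested |

A true log₂ fold-change *f* (second library over first) is split
symmetrically — ×2^(−f/2) on the first library, ×2^(+f/2) on the second — so
total library composition stays comparable. The miRNA read budget is shared
over mature + star mass, so the configured miRNA fraction is hit exactly in
expectation. Mature miRNA lengths are drawn 21/22/23 nt with mass
0.15/0.70/0.15, so the realized clean-read length mode is 22 nt
even when a single miRNA dominates the library. "Unannotated" contamination
is split between scaffold windows (genome-only territory) and a fixed pool
of reference-free sequences (unmatched), so every annotation category is
exercised; the pool is finite (200 sequences) so contaminant tags survive
the single-read filter the way recurring degradation products do.

Reads are insert + 3′ adapter truncated to the read length (42 nt, so the
full 12 nt adapter is present for any insert ≤ 30 nt), constant quality "I".
The generator does **not** model sequencing errors, quality-score
distributions, 5′ adapter artifacts, isomiR end-heterogeneity or
cross-mapping between paralogs — so passing tests demonstrate correctness of
the analysis logic under clean sampling noise, not robustness to platform
artifacts.

qPCR simulation: per replicate, reference Ct = baseline + N(0, σ²);
target Ct = that reference Ct + offset − log₂(level) + N(0, σ²). At σ = 0
the 2^(−ΔΔCt) estimator recovers configured levels exactly; at σ > 0 the
estimator is slightly upward-biased (it is an exponential of a noisy mean),
visible in Monte-Carlo at small replicate numbers.

## qPCR statistics

ΔΔCt is computed per biological replicate and then averaged — group means of
2^(−ΔΔCt) with SE = sd/√n over replicates — because error bars over
biological replicates require replicate-level values; the calibrator group
goes through the same formula (its mean is 1 only in the zero-noise limit).
Duncan's multiple range test uses the studentized range distribution at
Duncan's protection level α_p = 1 − (1−α)^(p−1); the least significant range
for p adjacent ordered means is R_p = q(1−α_p, p, df_err)·√(MSE/n). A pair
differs iff its span exceeds its R_p and no enclosing range is homogeneous;
consequently the homogeneous sets are maximal sorted intervals and each gets
one letter, which makes the letter display an exact encoding of the pairwise
decisions (verified against a brute-force all-pairs enumeration). Unbalanced
groups fall back to the harmonic-mean n with a warning. With zero error
variance every distinct pair of means is declared different (R_p = 0).

## Numerical choices

- Exact-test tails via `scipy.stats.nbinom` CDF/SF (numerically stable for
  large counts); the test suite checks them against direct log-space
  summation of the factorial formula at ≤ 1e−10 relative error.
- Percentages: decimal half-up rounding at 2 decimals (`Decimal`), not
  banker's rounding.
- Degenerate ANOVA input (all values identical) returns F = 0, p = 1 rather
  than NaN.
- Ties in classification resolve lexicographically; ties in Duncan intervals
  use a 1e−12 absolute slack so exact-boundary spans count as homogeneous.
- Reference construction rejects and redraws on the (vanishingly rare)
  collision where a miRNA arm appears in contaminant or off-target genome
  sequence, so simulator recovery tests can assert exact equality.

## Problem sizes used in the test and acceptance runs

Library-level simulations in the suite use 30–100 miRNAs and 2×10⁴–10⁵
reads per library at read level, and 500 miRNAs at 10⁶ reads per library at
count level; these sizes were chosen so the distributional properties under
test (type-I error, recovery, length mode, conservation) are already stable,
and the suite documents each choice next to the assertion.

## Known limitations

- One library per condition means the exact test quantifies sampling noise
  only; with the generator's negative-binomial overdispersion (φ = 0.1) the
  null rejection rate inflates well above nominal, which the suite asserts
  deliberately: per-library testing cannot see biological variance. Modern
  replicate-aware models are out of scope by design.
- Exact substring matching cannot tolerate sequencing errors or isomiR
  variation; it reproduces the "perfect match only" rule, not a sensitive
  aligner.
- The NE < 1 dual-library filter and the 0.01 imputation interact: a row
  with a single read in one library can pass the filter at large library
  sizes, with the fold-change artifact noted above.
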