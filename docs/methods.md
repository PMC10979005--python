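# Methods

## Data model and frequency estimation

A genotype table holds one row per individual (sample id, sex, population
label) and two allele columns per locus. Allele designations are opaque
strings under the ISFG repeat-count convention; microvariants ("9.3") are
kept verbatim and ordered numerically where the label parses as a number,
lexically otherwise. Sex-typing markers (Amelogenin) are parsed but
excluded from every STR statistic. A partial autosomal genotype (one of two
calls) is treated as a missing locus; the study design this package serves
never analyses half-calls.

Allele frequencies are counting estimators: counts divided by observed
chromosomes, where an X locus receives 2 chromosomes per female and 1 per
male (a male's "homozygous-looking" double call is collapsed to one copy on
input). Counts are stored as exact integers and rendered to 4 decimals only
on output, so combined products downstream carry no rounding drift. An
empty stratum raises an error rather than returning silent zeros.

Male X calls are screened before analysis. The default policy,
`exclude_sample`, removes a male with any X dropout or two distinct X
alleles from the X analyses entirely — the handling applied to dropout
samples in reference-database practice; `exclude_locus_call` (drop the one
call) and `error` are available because per-locus exclusion is the common
alternative.

## Forensic efficiency parameters

With `a = Σp_i²`, `b = Σp_i³`, `c = Σp_i⁴`:

| quantity | formula | notes |
|---|---|---|
| GD = He | `n/(n−1)·(1−a)` | unbiased correction default; biased variant by flag |
| PIC | `1 − a − a² + c` | Botstein form |
| MP, PD | `Σ f_g²`, `1 − MP` | observed genotype frequencies by default; HWE-expected `2a² − c` optional |
| PE_trio | `h²(1 − 2hH²)`, h = Ho, H = 1−h | heterozygosity convention (PowerStats tradition) |
| PE_trio (frequency) | exact enumeration | see below |
| PE_duo | `Σp²(1−p)² + Σ_{i<j}2p_ip_j(1−p_i−p_j)²` | = enumeration over child × man |
| TPI | `1/(2H)` | infinite at Ho = 1, reported as `inf` |

Exclusion powers have competing conventions in the literature and the
tools that implement them rarely print their formula. The package
therefore treats the *pedigree scenario* as the definition: an operation's
value must equal a brute-force enumeration over all genotype
configurations under HWE (mutation ignored, which matches the exclusion
literature). The test suite carries independent loop-based enumerations
and requires agreement to 1e-12; closed forms are merely fast paths.

### X-chromosome scenarios

Males are hemizygous, so each scenario differs from its autosomal
counterpart:

- **PD_male** `= 1 − a` (a male profile is one allele);
  **PD_female** `= 1 − 2a² + c` (complement of the female HWE genotype
  matching probability).
- **Trio MEC** (mother, daughter, alleged father): the paternal allele is
  deducible from mother and daughter except when the mother carries both
  daughter alleles, in which case either could have been maternal. The
  alleged father (one allele) is excluded iff it is incompatible.
  Enumeration reduces to `1 − a − a² + c` — identical to PIC, a known
  identity for X-linked trios. The two cited variants of this quantity
  (Kishida; Desmarais) are exposed as separate operations, one computed by
  enumeration and one by the closed form; they agree to machine precision.
- **Duo MEC** (father–daughter, mother untyped): the man's allele must
  miss both daughter alleles; closed form `1 − 2a + b`.
- **Krüger deficiency MEC** (mother, daughter, paternal grandmother): the
  grandmother stands in for the untyped man and must carry a compatible
  paternal allele. Being diploid she is harder to exclude: each trio
  configuration contributes `(1 − Σ_S p)²` instead of `(1 − Σ_S p)`, so
  MEC_Krüger ≤ MEC_trio always.

Combined values multiply complements: `1 − Π(1 − v_l)` per parameter,
`CMP = Π MP_l`. Haplotype diversity over male multi-locus profiles uses
the unbiased `n/(n−1)(1 − Σf_h²)`; when all profiles are distinct this is
exactly 1.

## Exact tests

All tests are conditional exact tests under the probability ordering: the
p-value is the null probability of outcomes no more probable than observed,
conditioning on allele (margin) counts. Ties are included (computed with a
relative tolerance of 1e-9 on the log-probability, far wider than float
error and far narrower than any real probability gap).

**HWE.** The conditional null given allele counts is the random-pairing
law `P(T) = n!·2^h·Πa_i! / ((2n)!·Πn_ij!)`. Small spaces (≤ a configurable
table bound, default 10⁶, with ≤12 alleles and a node budget that bounds
the tree walk) are fully enumerated with the statistic accumulated
incrementally during the recursion; the enumeration asserts that its total
mass is 1 to 1e-8, a strong internal correctness check. Larger spaces use
a Markov chain of random transpositions of the gene-copy vector —
uniform over copy arrangements, hence exactly the random-pairing law on
tables — with defaults of 10⁶ steps and 10⁵ burn-in and a batch-means
standard error; or an i.i.d. pairing resampler (`method="permutation"`,
vectorized, exact binomial SE), which is what large calibration
experiments use. Monomorphic input returns p = 1 with a `degenerate`
marker. Every Monte-Carlo result carries its seed and standard error.

**LD, phase-known (male X haplotypes).** An r×c contingency table with
fixed margins; full enumeration (generalizing the two-sided Fisher exact
test, against which the 2×2 case is verified) or a seeded permutation of
one locus's alleles beyond the bound.

**LD, unphased diploid genotypes (females).** Two-locus haplotype
frequencies are fitted by EM (tolerance 1e-7, ≤1000 iterations; phase
resolutions flattened to index arrays so an iteration is a few vectorized
scatter/gathers). The likelihood-ratio statistic compares the EM fit with
linkage equilibrium (product of allele frequencies); significance comes
from permuting one locus's genotypes between individuals (default 10⁴
permutations, seeded), which preserves both single-locus genotype
distributions. The product-frequency EM start is a stationary point for
perfectly symmetric data (e.g. all double heterozygotes), so EM runs from
the product start plus two deterministically jittered restarts and keeps
the best likelihood. Note that for data in which *every* individual is
identical, any permutation reproduces the data and the permutation p-value
is necessarily 1 — maximal-association checks therefore need genotype
variety.

**Multiple testing.** Bonferroni threshold α/m with m always the actual
number of tests performed; pair enumeration yields all C(k,2) unordered
locus pairs in deterministic order (171 for a 19-locus panel).

### Calibration conditions

Type-I-error calibration uses STR-realistic 6-allele loci
(Dirichlet(5) frequencies drawn fresh per replicate), 50 diploids (HWE) or
80 haploid males (LD), Monte-Carlo p-values `(b+1)/(B+1)` with B = 2000
(HWE pairing sampler) or 999 (LD permutation), and rejection at p ≤ 0.05.
Under these conditions the MC p-value of a continuous-enough statistic is
uniform on its grid and the expected rejection rate is 100/2001 ≈ 0.05
(HWE) and 50/1000 = 0.05 (LD); residual discreteness of the conditional
distributions can only push the rate *down*. At 2-allele loci the exact
tests are far more discrete and no correct exact test calibrates tightly —
which is why the calibration experiments use multi-allelic loci, as real
STR panels are.

## Population structure

- **Weir–Cockerham θ**: variance components a, b, c accumulated over every
  allele of every locus; θ = Σa/Σ(a+b+c). Negative estimates (expected in
  weakly differentiated samples) are reported unclamped, with a clamped
  view for tree/ordination input. Optional significance by permuting
  individuals between two groups. Populations under a minimum size give
  NaN entries with a warning.
- **Nei (1972) standard distance**: identities Jxy, Jx, Jy averaged over
  shared loci *before* the log-ratio (the two orders differ; this is the
  original definition). Disjoint allele sets give an explicit +inf.
- **Classical MDS** (Torgerson/Gower): double-center −D²/2,
  eigendecompose, embed on the positive eigenvalues; negative eigenvalues
  are reported, k is reduced with a warning when fewer positive axes
  exist, and coordinates carry a "sign/rotation arbitrary" note —
  comparisons must use reconstructed distances, never raw axes. Verified
  against scikit-bio's PCoA.
- **Neighbor joining**: scikit-bio's Saitou–Nei implementation behind the
  module surface, returning Newick; infinite distances are rejected with
  instructions to cap them. Additivity is the oracle: for tree-metric
  inputs the NJ tree's path lengths must reproduce the input matrix to
  1e-9.
- **Small-group pooling**: population labels under a configurable
  threshold (default 10 individuals) are merged into "Other" before
  structure analyses. The threshold is exposed because practice varies
  (10 and 20 both appear in the field); no single default is privileged.

## Synthetic data generator

The generator emulates the shape of a West-African STR reference study:
396 autosomal individuals (272 male / 124 female) on 20 loci of 8–28
alleles, and 292 X individuals (123 female / 169 male) on 19 loci of 6–43
alleles; several weakly differentiated subpopulations drawn from a shared
ancestral Dirichlet spectrum by the Balding–Nichols model
(Dirichlet(p̄(1−F)/F): mean p̄, variance p̄(1−p̄)F); HWE genotype sampling
(two draws per diploid, one per hemizygous male); STR-style integer labels
with a configurable fraction of ".3" microvariants; and male X dropout
injected per call at a rate defaulting to 2/(169·19) — about two dropout
events per study, the rate such studies report. One global seed fans out
into per-stage substreams (frequencies, genotypes, dropout) so stages are
independently reproducible.

What the generator does *not* emulate: mutation, stutter and typing
artifacts, genuine linkage between X loci, departures from HWE within
subpopulations, and relatedness structure. Tests passing on this generator
therefore validate the estimators and test machinery under their stated
models, not robustness to those real-data complications.

## Pipelines

`run_autosomal_pipeline` and `run_x_pipeline` are pure functions of
(table, config): they serialize their config into the output directory,
log sample counts at each filter step, and emit machine-readable CSV/JSON
(frequency tables per stratum, per-locus parameter tables, HWE/LD test
matrices with Bonferroni decisions, distance matrices, Newick trees, MDS
coordinates, and a combined-values summary). Display rounding is 4
decimals for frequencies and per-locus parameters and 15 significant
digits for combined values. Double-running a pipeline on the same input
and config produces byte-identical outputs.

Default problem sizes in the test suite and the acceptance script are
scaled to desk scale — Markov chains of 2×10⁴–2×10⁵ steps, hundreds of
permutations per test, 1000-replicate calibrations — chosen so the whole
battery runs in minutes on one CPU while leaving Monte-Carlo standard
errors well inside every asserted tolerance. Production defaults
(10⁶-step chains, 10⁴ permutations) match the scale of the standard
population-genetics tools.

## Known limitations

- Exclusion probabilities ignore mutation and silent alleles; they are
  genotype-incompatibility probabilities only.
- The genotypic LD permutation test is approximate in the sense of any
  permutation test (p has a 1/(B+1) floor) and EM may, despite restarts,
  miss a global optimum on pathological data; non-convergence is flagged
  on the result rather than raised.
- θ permutation p-values are one-sided (differentiation larger than
  observed).
- The 20-vs-21-locus ambiguity of autosomal identification panels is
  resolved by the panel definition itself: Amelogenin is never an STR
  statistic locus, so a "21-plex" yields 20 STR loci.
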