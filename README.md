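# forensicstr

Population statistics for forensic short-tandem-repeat (STR) panels:
allele-frequency estimation, the per-locus and combined efficiency
parameters used in human identification and paternity casework, exact
Hardy–Weinberg and linkage-disequilibrium tests, and between-population
structure analysis — for both autosomal and X-chromosome markers.

## Who it is for

Forensic genetics labs building an allele-frequency reference database for
a population, and population geneticists comparing STR datasets across
groups. The package covers the full analysis a reference-database study
runs after genotyping: a ~400-individual sample typed on a 20-locus
autosomal identification panel and a 19-locus X-STR panel, with
sex-structured X data (females diploid, males hemizygous) and the
occasional male X dropout.

## What it computes

Per autosomal locus, from allele frequencies `p_i` (n observed
chromosomes) and observed genotype counts:

- gene diversity / expected heterozygosity `GD = He = n/(n−1)·(1 − Σp_i²)`
- polymorphism information content `PIC = 1 − Σp² − (Σp²)² + Σp⁴`
- matching probability `MP = Σ_g f_g²` over genotype frequencies, and the
  power of discrimination `PD = 1 − MP`
- powers of exclusion for parent–child duos and mother–child–father trios
  (heterozygosity-based conventions by default, frequency-based variants by
  exact enumeration under HWE), and the typical paternity index
  `TPI = 1/(2(1−Ho))`

Per X locus: sex-specific powers of discrimination
(`PD_male = 1 − Σp²`, `PD_female = 1 − 2(Σp²)² + Σp⁴`) and the four mean
exclusion chances (MEC) of the X-STR kinship literature — trio
(Kishida / Desmarais), father–daughter duo, and the paternal-grandmother
deficiency case (Krüger) — each defined by exact enumeration of its
pedigree scenario.

Panel-wide: combined matching probability `CMP = Π MP_l` and combined
exclusion/discrimination powers `1 − Π(1 − v_l)`.

Testing and structure: exact conditional HWE tests (full enumeration or a
Guo–Thompson-style Markov chain / i.i.d. pairing sampler beyond the
enumeration bound), probability-ordering exact independence tests on male
haplotype tables, EM + permutation likelihood-ratio LD tests for unphased
female genotypes, Bonferroni correction, Weir–Cockerham θ (FST), Nei's
(1972) standard distance, classical MDS, and neighbor-joining trees with
Newick output. A seeded synthetic-genotype generator (Balding–Nichols
subpopulation model, STR-style allele labels, male X dropout) provides
study-shaped data with known truth.

## Worked example

```python
from forensicstr import (AlleleFrequencySpectrum, gene_diversity, pic,
                         power_of_exclusion_duo, mec_kishida,
                         mec_desmarais_duo, hwe_exact_test)

sp = AlleleFrequencySpectrum("TH01", {"6": 91, "7": 172, "8": 64,
                                      "9": 101, "9.3": 231, "10": 13})
print("n_chrom ", sp.n_chrom)
print("GD      ", round(gene_diversity(sp), 4))
print("PIC     ", round(pic(sp), 4))
print("PE_duo  ", round(power_of_exclusion_duo(sp), 4))
print("MEC trio", round(mec_kishida(sp), 4))
print("MEC duo ", round(mec_desmarais_duo(sp), 4))
res = hwe_exact_test({("A", "A"): 1, ("a", "a"): 1})
print("exact HWE p =", res.p_value)
```

prints

```
n_chrom  672
GD       0.7671
PIC      0.7304
PE_duo   0.3724
MEC trio 0.7304
MEC duo  0.596
exact HWE p = 0.3333333333333332
```

The six-allele locus (336 individuals, 672 chromosomes) has a 76.7% chance
that two random gene copies differ (GD) and excludes a random non-father in
37.2% of duo cases. The trio MEC equals PIC — the pedigree enumeration
reduces algebraically to the PIC expression, a known identity for X-linked
trio cases. The final line is the exact conditional HWE p-value for the
smallest non-trivial dataset (two homozygotes for different alleles): of
the two genotype tables consistent with the allele counts, the observed one
carries exactly 1/3 of the conditional probability.

Command-line pipelines mirror the library:

```sh
forensicstr simulate --seed 1 --kind x data.tsv
forensicstr forensic-x --seed 1 data.tsv out/
```

`out/` then holds the three frequency strata (pooled / female / male),
per-locus X parameters, female HWE tests, the 171-pair male and female LD
matrices, and a combined-values summary.

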