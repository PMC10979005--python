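"""X-chromosome STR forensic parameters.

Males are hemizygous, so X markers behave haploid in men and diploid in
women; every quantity here is scenario-specific:

* PD_male  = 1 - Σp²            (a male profile is his single allele)
* PD_female = 1 - 2(Σp²)² + Σp⁴ (complement of the HWE genotype match
  probability in women)
* mean exclusion chances (MEC) for the kinship scenarios of the X-STR
  literature, each *defined* by exact enumeration of the pedigree under HWE
  with mutation ignored:

  - trio, mother + daughter + alleged father (hemizygous): the paternal
    allele is deduced from mother and daughter, ambiguously when the mother
    carries both daughter alleles; the man is excluded iff his allele is
    incompatible.  The Kishida entry computes this by enumeration; the
    Desmarais entry uses the closed form 1 - a - a² + c
    (a = Σp², c = Σp⁴), which equals the enumeration.
  - duo, father + daughter without the mother: the man is excluded iff his
    allele is absent from the daughter's genotype; closed form 1 - 2a + b.
  - deficiency case (Krüger), mother + daughter + paternal grandmother: the
    grandmother stands in for the untyped alleged father and must carry a
    compatible paternal allele; being diploid she is harder to exclude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .forensic import gene_diversity, pic
from .markers import AlleleFrequencySpectrum

__all__ = [
    "XLocusForensicStats",
    "pd_male",
    "pd_female",
    "mec_kruger",
    "mec_kishida",
    "mec_desmarais",
    "mec_desmarais_duo",
    "power_of_exclusion_x",
    "haplotype_diversity",
    "x_locus_stats",
    "combine_x",
]


def _moments(spectrum: AlleleFrequencySpectrum) -> tuple[float, float, float]:
    p = spectrum.freqs
    return float(np.sum(p**2)), float(np.sum(p**3)), float(np.sum(p**4))


def pd_male(spectrum: AlleleFrequencySpectrum) -> float:
    a, _, _ = _moments(spectrum)
    return 1.0 - a


def pd_female(spectrum: AlleleFrequencySpectrum) -> float:
    a, _, c = _moments(spectrum)
    return 1.0 - 2.0 * a * a + c


def mec_desmarais_duo(spectrum: AlleleFrequencySpectrum) -> float:
    """Father-daughter duo MEC: 1 - 2Σp² + Σp³."""
    a, b, _ = _moments(spectrum)
    return 1.0 - 2.0 * a + b


def mec_desmarais(spectrum: AlleleFrequencySpectrum) -> float:
    """Trio MEC, closed form 1 - a - a² + c (a = Σp², c = Σp⁴).

    Derivation from the enumeration: the man is excluded with probability
    (1 - p_f) except in the ambiguous configurations (mother carries both
    daughter alleles, total mass Σ_{f≠m} p_f² p_m² = a² - c) where the
    compatible set gains the maternal allele; hence
    (1 - a) - (a² - c).
    """
    a, _, c = _moments(spectrum)
    return 1.0 - a - a * a + c


def _paternal_sets(p: np.ndarray):
    """Yield (weight, compatible-paternal-allele frequency mass) over trio
    configurations (maternal transmitted mi, maternal other mj, paternal f).
    """
    k = len(p)
    for mi in range(k):
        for mj in range(k):
            pm = p[mi] * p[mj]
            if pm == 0.0:
                continue
            for f in range(k):
                w = pm * p[f]
                if w == 0.0:
                    continue
                # daughter = {f, mi}; ambiguous iff het and mother has both
                if f != mi and mj == f:
                    yield w, p[f] + p[mi]
                else:
                    yield w, p[f]


def mec_kishida(spectrum: AlleleFrequencySpectrum) -> float:
    """Trio MEC by exact pedigree enumeration (hemizygous alleged father)."""
    p = spectrum.freqs
    return float(sum(w * (1.0 - ps) for w, ps in _paternal_sets(p)))


def mec_kruger(spectrum: AlleleFrequencySpectrum) -> float:
    """Deficiency-case MEC (paternal grandmother typed instead of the man).

    The grandmother is diploid; she is excluded iff *neither* of her alleles
    lies in the compatible paternal set, so each trio configuration
    contributes (1 - Σ_S p)² instead of (1 - Σ_S p).
    """
    p = spectrum.freqs
    return float(sum(w * (1.0 - ps) ** 2 for w, ps in _paternal_sets(p)))


def power_of_exclusion_x(ho_female: float) -> float:
    """Heterozygosity-based PE at an X locus from female observed Ho."""
    h = ho_female
    H = 1.0 - h
    return h * h * (1.0 - 2.0 * h * H * H)


def haplotype_diversity(haplotypes: Sequence[tuple]) -> float:
    """Unbiased diversity of multi-locus male haplotypes.

    HD = n/(n-1) (1 - Σ f_h²) over the distinct observed profiles.
    """
    n = len(haplotypes)
    if n < 2:
        raise ValueError("haplotype diversity undefined for n < 2")
    counts: dict = {}
    for h in haplotypes:
        key = tuple(h)
        counts[key] = counts.get(key, 0) + 1
    s = sum((c / n) ** 2 for c in counts.values())
    return n / (n - 1) * (1.0 - s)


@dataclass(frozen=True)
class XLocusForensicStats:
    locus: str
    n_chrom: int
    n_alleles: int
    Ho_female: float
    GD: float
    PIC: float
    PD_female: float
    PD_male: float
    PE: float
    MEC_kruger: float
    MEC_kishida: float
    MEC_desmarais: float
    MEC_desmarais_duo: float

    def as_dict(self) -> dict:
        return {
            "locus": self.locus, "n_chrom": self.n_chrom,
            "n_alleles": self.n_alleles, "Ho_female": self.Ho_female,
            "GD": self.GD, "PIC": self.PIC,
            "PD_female": self.PD_female, "PD_male": self.PD_male,
            "PE": self.PE, "MEC_kruger": self.MEC_kruger,
            "MEC_kishida": self.MEC_kishida,
            "MEC_desmarais": self.MEC_desmarais,
            "MEC_desmarais_duo": self.MEC_desmarais_duo,
        }


def x_locus_stats(
    spectrum: AlleleFrequencySpectrum,
    female_genotype_counts: Mapping[tuple[str, str], int] | None = None,
) -> XLocusForensicStats:
    """All per-locus X parameters from a (pooled) spectrum.

    Observed female heterozygosity, and the PE derived from it, need the
    female genotype counts; they are NaN when those are not supplied.
    """
    if female_genotype_counts:
        tot = sum(female_genotype_counts.values())
        ho = sum(c for (x, y), c in female_genotype_counts.items() if x != y) / tot
        pe = power_of_exclusion_x(ho)
    else:
        ho = pe = float("nan")
    return XLocusForensicStats(
        locus=spectrum.locus,
        n_chrom=spectrum.n_chrom,
        n_alleles=len(spectrum),
        Ho_female=ho,
        GD=gene_diversity(spectrum),
        PIC=pic(spectrum),
        PD_female=pd_female(spectrum),
        PD_male=pd_male(spectrum),
        PE=pe,
        MEC_kruger=mec_kruger(spectrum),
        MEC_kishida=mec_kishida(spectrum),
        MEC_desmarais=mec_desmarais(spectrum),
        MEC_desmarais_duo=mec_desmarais_duo(spectrum),
    )


def combine_x(stats: Sequence[XLocusForensicStats]) -> dict[str, float]:
    """Panel-wide combined X values, 1 - Π(1 - v) per parameter.

    Combined discrimination powers multiply the per-locus *match*
    probabilities (the complements), which is the same arithmetic.
    Permutation-invariant in locus order.
    """
    if not stats:
        raise ValueError("need at least one X locus")

    def comb(vals):
        return 1.0 - float(np.prod([1.0 - v for v in vals]))

    out = {
        "CPD_female": comb([s.PD_female for s in stats]),
        "CPD_male": comb([s.PD_male for s in stats]),
        "CMEC_kruger": comb([s.MEC_kruger for s in stats]),
        "CMEC_kishida": comb([s.MEC_kishida for s in stats]),
        "CMEC_desmarais": comb([s.MEC_desmarais for s in stats]),
        "CMEC_desmarais_duo": comb([s.MEC_desmarais_duo for s in stats]),
    }
    pes = [s.PE for s in stats if not np.isnan(s.PE)]
    out["CPE"] = comb(pes) if pes else float("nan")
    return out
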