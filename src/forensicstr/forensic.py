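"""Forensic efficiency parameters for autosomal STR loci.

Per-locus quantities, with allele frequencies p_i and n = observed
chromosomes:

* gene diversity / expected heterozygosity  GD = He = n/(n-1) (1 - Σp_i²)
  (unbiased small-sample correction; the biased 1 - Σp_i² variant is a flag)
* polymorphism information content          PIC = 1 - Σp² - (Σp²)² + Σp⁴
* matching probability                      MP = Σ_g f_g²  over genotype
  frequencies (observed by default, HWE-expected optional); PD = 1 - MP
* powers of exclusion for a parent-child duo and a mother-child-father trio,
  and the typical paternity index TPI = 1/(2(1-Ho)).

Exclusion powers come in two conventions: the heterozygosity-based forms of
the PowerStats tradition (defaults) and frequency-based forms computed by
exact enumeration over genotype configurations under HWE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .markers import AlleleFrequencySpectrum

__all__ = [
    "LocusForensicStats",
    "CombinedForensicStats",
    "gene_diversity",
    "pic",
    "match_probability",
    "heterozygosities",
    "power_of_exclusion_trio",
    "power_of_exclusion_duo",
    "typical_paternity_index",
    "locus_stats",
    "combine",
]

#: warn below this many observed chromosomes
SMALL_SAMPLE_CHROMOSOMES = 20


def gene_diversity(spectrum: AlleleFrequencySpectrum, *,
                   unbiased: bool = True) -> float:
    """Gene diversity (= expected heterozygosity) from allele frequencies."""
    n = spectrum.n_chrom
    if n < 2:
        raise ValueError("gene diversity undefined for n_chrom < 2")
    p = spectrum.freqs
    gd = 1.0 - float(np.sum(p * p))
    if unbiased:
        gd *= n / (n - 1)
    return gd


def pic(spectrum: AlleleFrequencySpectrum) -> float:
    """Polymorphism information content (Botstein form)."""
    p = spectrum.freqs
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    return 1.0 - s2 - s2 * s2 + s4


def match_probability(
    genotype_counts: Mapping[tuple[str, str], int] | None = None,
    spectrum: AlleleFrequencySpectrum | None = None,
    *,
    expected: bool = False,
) -> tuple[float, float]:
    """Matching probability and power of discrimination.

    Default: MP = Σ f_g² over *observed* genotype relative frequencies.
    With ``expected=True`` the genotype frequencies are the HWE expectations
    from ``spectrum`` (p_i² and 2 p_i p_j).
    """
    if expected:
        if spectrum is None:
            raise ValueError("expected=True requires a spectrum")
        p = spectrum.freqs
        s2 = float(np.sum(p * p))
        s4 = float(np.sum(p**4))
        # Σ (p_i²)² + Σ_{i<j} (2 p_i p_j)² = 2 s2² - s4
        mp = 2 * s2 * s2 - s4
    else:
        if not genotype_counts:
            raise ValueError("no observed genotypes")
        tot = sum(genotype_counts.values())
        mp = sum((c / tot) ** 2 for c in genotype_counts.values())
    return mp, 1.0 - mp


def heterozygosities(
    genotype_counts: Mapping[tuple[str, str], int],
    spectrum: AlleleFrequencySpectrum,
    *,
    unbiased: bool = True,
) -> tuple[float, float]:
    """Observed and expected heterozygosity from the same stratum."""
    tot = sum(genotype_counts.values())
    if tot == 0:
        raise ValueError("no observed genotypes")
    het = sum(c for (a, b), c in genotype_counts.items() if a != b)
    return het / tot, gene_diversity(spectrum, unbiased=unbiased)


def power_of_exclusion_trio(
    ho: float | None = None,
    spectrum: AlleleFrequencySpectrum | None = None,
    *,
    convention: str = "heterozygosity",
) -> float:
    """Power of exclusion in a mother-child-alleged-father trio.

    ``heterozygosity`` (default): PE = h²(1 - 2 h H²), h = Ho, H = 1 - h.
    ``frequency``: exact enumeration under HWE — the true paternal allele is
    deduced from mother and child; an unrelated man is excluded iff he
    carries no allele compatible with paternity.
    """
    if convention == "heterozygosity":
        if ho is None:
            raise ValueError("heterozygosity convention needs Ho")
        if not 0.0 <= ho <= 1.0:
            raise ValueError("Ho must lie in [0,1]")
        h = ho
        H = 1.0 - h
        return h * h * (1.0 - 2.0 * h * H * H)
    if convention == "frequency":
        if spectrum is None:
            raise ValueError("frequency convention needs a spectrum")
        return _pe_trio_enumeration(spectrum.freqs)
    raise ValueError(f"unknown convention {convention!r}")


def _pe_trio_enumeration(p: np.ndarray) -> float:
    """Trio exclusion probability by enumeration over (mother, paternal
    allele, maternal transmitted allele) and the unrelated man's genotype.

    The compatible-paternal set S is {f} when the child's paternal allele f
    is unambiguous, or both child alleles when the mother carries both (so
    either could have been maternal).  The man is excluded iff neither of
    his two alleles is in S: probability (1 - Σ_{S} p)².
    """
    k = len(p)
    total = 0.0
    for mi in range(k):            # maternal transmitted allele
        for mj in range(k):        # maternal untransmitted allele
            pm = p[mi] * p[mj]     # ordered mother genotype prob
            for f in range(k):     # paternal allele
                w = pm * p[f]
                if w == 0.0:
                    continue
                child = {f, mi}
                if f != mi and mj in child and mi != mj:
                    ps = p[f] + p[mi]   # ambiguous: mother carries both
                else:
                    ps = p[f]
                total += w * (1.0 - ps) ** 2
    return total


def power_of_exclusion_duo(spectrum: AlleleFrequencySpectrum) -> float:
    """Exclusion power for a parent-child duo (other parent untyped).

    Probability that a random man shares no allele with a random child:
    Σ_i p_i²(1-p_i)² + Σ_{i<j} 2 p_i p_j (1-p_i-p_j)².
    """
    p = spectrum.freqs
    k = len(p)
    total = float(np.sum(p**2 * (1.0 - p) ** 2))
    for i in range(k):
        for j in range(i + 1, k):
            total += 2.0 * p[i] * p[j] * (1.0 - p[i] - p[j]) ** 2
    return total


def typical_paternity_index(ho: float) -> float:
    """TPI = 1/(2H) with H the observed homozygosity; inf when Ho = 1."""
    if not 0.0 <= ho <= 1.0:
        raise ValueError("Ho must lie in [0,1]")
    H = 1.0 - ho
    return math.inf if H == 0.0 else 1.0 / (2.0 * H)


@dataclass(frozen=True)
class LocusForensicStats:
    locus: str
    n_chrom: int
    n_alleles: int
    Ho: float
    He: float
    GD: float
    PIC: float
    MP: float
    PD: float
    PE_trio: float
    PE_duo: float
    TPI: float

    def as_dict(self) -> dict:
        return {
            "locus": self.locus, "n_chrom": self.n_chrom,
            "n_alleles": self.n_alleles, "Ho": self.Ho, "He": self.He,
            "GD": self.GD, "PIC": self.PIC, "MP": self.MP, "PD": self.PD,
            "PE_trio": self.PE_trio, "PE_duo": self.PE_duo, "TPI": self.TPI,
        }


def locus_stats(
    genotype_counts: Mapping[tuple[str, str], int],
    spectrum: AlleleFrequencySpectrum,
    *,
    mp_expected: bool = False,
    pe_convention: str = "heterozygosity",
    warn_small: bool = True,
) -> LocusForensicStats:
    """Bundle all autosomal per-locus parameters for one stratum."""
    if warn_small and spectrum.n_chrom < SMALL_SAMPLE_CHROMOSOMES:
        import warnings

        warnings.warn(
            f"{spectrum.locus}: only {spectrum.n_chrom} chromosomes observed",
            stacklevel=2,
        )
    ho, he = heterozygosities(genotype_counts, spectrum)
    mp, pd_ = match_probability(genotype_counts, spectrum, expected=mp_expected)
    pe3 = power_of_exclusion_trio(ho, spectrum, convention=pe_convention)
    return LocusForensicStats(
        locus=spectrum.locus,
        n_chrom=spectrum.n_chrom,
        n_alleles=len(spectrum),
        Ho=ho,
        He=he,
        GD=gene_diversity(spectrum),
        PIC=pic(spectrum),
        MP=mp,
        PD=pd_,
        PE_trio=pe3,
        PE_duo=power_of_exclusion_duo(spectrum),
        TPI=typical_paternity_index(ho),
    )


@dataclass(frozen=True)
class CombinedForensicStats:
    CMP: float
    CPD: float
    CPE_trio: float
    CPE_duo: float
    loci_used: tuple[str, ...]

    def as_dict(self) -> dict:
        return {
            "CMP": self.CMP, "CPD": self.CPD, "CPE_trio": self.CPE_trio,
            "CPE_duo": self.CPE_duo, "loci_used": list(self.loci_used),
        }


def combine(stats: Sequence[LocusForensicStats]) -> CombinedForensicStats:
    """Panel-wide combined values under locus independence.

    CMP = Π MP_l (and CPD = 1 - CMP); each combined exclusion power is
    1 - Π(1 - PE_l).
    """
    if not stats:
        raise ValueError("need at least one locus")
    cmp_ = float(np.prod([s.MP for s in stats]))
    cpe3 = 1.0 - float(np.prod([1.0 - s.PE_trio for s in stats]))
    cpe2 = 1.0 - float(np.prod([1.0 - s.PE_duo for s in stats]))
    return CombinedForensicStats(
        CMP=cmp_, CPD=1.0 - cmp_, CPE_trio=cpe3, CPE_duo=cpe2,
        loci_used=tuple(s.locus for s in stats),
    )
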