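"""Seeded genotype simulator with known truth.

Emulates the shape of a West-African forensic reference dataset: ~400
diploid individuals typed on a 20-locus autosomal panel, and a sex-
structured X panel (123 females / 169 males) of 19 loci carrying 6-43
alleles each, several weakly differentiated subpopulations (Balding-Nichols
divergence from a shared ancestral spectrum), STR-style allele labels with
occasional ".3" microvariants, and rare male X dropout.

One global seed fans out into independent substreams per stage
(frequencies, genotypes, dropout) so stages can be tested in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .markers import (
    AlleleFrequencySpectrum,
    GenotypeTable,
    Linkage,
    MarkerDef,
    Sex,
)

__all__ = [
    "SimConfig",
    "draw_subpop_frequencies",
    "sample_genotypes",
    "inject_dropout",
    "simulate_autosomal_table",
    "simulate_x_table",
    "random_spectrum",
]


@dataclass
class SimConfig:
    """Knobs of the generator; defaults emulate the reference study shape."""

    seed: int = 0
    n_loci_autosomal: int = 20
    n_loci_x: int = 19
    #: X loci carry 6-43 alleles, autosomal loci 8-28 (the study's ranges)
    alleles_min: int = 6
    alleles_max: int = 43
    alleles_min_autosomal: int = 8
    alleles_max_autosomal: int = 28
    dirichlet_concentration: float = 1.0
    #: (label, n_individuals, Balding-Nichols F) per subpopulation
    subpopulations: tuple[tuple[str, int, float], ...] = (
        ("Gur", 331, 0.01),
        ("Mande", 54, 0.01),
        ("Other", 11, 0.01),
    )
    n_females_autosomal: int = 124
    n_males_autosomal: int = 272
    n_females_x: int = 123
    n_males_x: int = 169
    #: per-call male X blanking probability; default targets ~2 dropouts
    #: over 169 males x 19 loci, the rate seen in the reference data
    dropout_rate: float = 2.0 / (169 * 19)
    microvariant_fraction: float = 0.1

    def validate(self) -> None:
        for _, size, f in self.subpopulations:
            if size < 1:
                raise ValueError("subpopulation size must be >= 1")
            if not 0.0 < f < 1.0:
                raise ValueError("F must lie in (0,1)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0,1)")

    def substream(self, stage: str) -> np.random.Generator:
        # stable across processes (unlike built-in str hash)
        import zlib

        key = zlib.crc32(stage.encode()) % 2**31
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


def _allele_labels(k: int, rng: np.random.Generator,
                   microvariant_fraction: float) -> list[str]:
    """Realistic STR repeat designations: consecutive integers from a random
    start, a fraction turned into ".3" microvariants."""
    start = int(rng.integers(5, 12))
    labels = []
    for i in range(k):
        base = start + i
        if rng.random() < microvariant_fraction:
            labels.append(f"{base}.3")
        else:
            labels.append(str(base))
    return labels


def random_spectrum(
    k: int,
    rng: np.random.Generator,
    *,
    n_chrom: int = 1000,
    concentration: float = 1.0,
    microvariant_fraction: float = 0.0,
) -> AlleleFrequencySpectrum:
    """Random Dirichlet spectrum rendered as integer counts (n_chrom total)."""
    p = rng.dirichlet(np.full(k, concentration))
    counts = rng.multinomial(n_chrom - k, p) + 1  # every allele observed
    labels = _allele_labels(k, rng, microvariant_fraction)
    return AlleleFrequencySpectrum("SIM", dict(zip(labels, counts.tolist())))


def draw_subpop_frequencies(
    ancestral: np.ndarray, F: float, rng: np.random.Generator
) -> np.ndarray:
    """Balding-Nichols subpopulation frequencies.

    Dirichlet(p̄_i (1-F)/F): expectation p̄, per-allele variance
    p̄_i(1-p̄_i)F.  A degenerate ancestral spectrum is returned unchanged.
    """
    if not 0.0 < F < 1.0:
        raise ValueError("F must lie in (0,1)")
    ancestral = np.asarray(ancestral, dtype=float)
    support = ancestral > 0.0
    if support.sum() == 1:
        return ancestral.copy()
    out = np.zeros_like(ancestral)
    out[support] = rng.dirichlet(ancestral[support] * (1.0 - F) / F)
    return out


def sample_genotypes(
    freqs: np.ndarray,
    labels: Sequence[str],
    n: int,
    ploidy_model: str,
    rng: np.random.Generator,
) -> list[tuple[str | None, str | None]]:
    """Draw HWE genotypes: ``diploid`` = two independent allele draws;
    ``haploid`` = one draw (the second slot stays None)."""
    k = len(labels)
    if ploidy_model == "diploid":
        draws = rng.choice(k, size=(n, 2), p=freqs)
        return [(labels[a], labels[b]) for a, b in draws]
    if ploidy_model == "haploid":
        draws = rng.choice(k, size=n, p=freqs)
        return [(labels[a], None) for a in draws]
    raise ValueError(f"unknown ploidy model {ploidy_model!r}")


def inject_dropout(
    table: GenotypeTable, rate: float, seed: int
) -> tuple[GenotypeTable, list[tuple[str, str]]]:
    """Blank male X calls independently with probability ``rate``.

    Returns the modified table and the log of (sample, locus) sites blanked
    — the ground truth against which the dropout validator is checked.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0,1)")
    rng = np.random.default_rng(seed)
    df = table.data.copy()
    injected: list[tuple[str, str]] = []
    x_loci = [m for m in table.panel if m.linkage is Linkage.X_LINKED]
    males = df["Sex"].astype(str) == Sex.MALE.value
    for idx in df.index[males]:
        for m in x_loci:
            if df.at[idx, f"{m.name}_1"] is None:
                continue
            if rng.random() < rate:
                df.at[idx, f"{m.name}_1"] = None
                df.at[idx, f"{m.name}_2"] = None
                injected.append((str(df.at[idx, "SampleID"]), m.name))
    return GenotypeTable(table.panel, df, table.provenance), injected


def _build_panel_frequencies(config: SimConfig, n_loci: int, prefix: str,
                             linkage: Linkage):
    """Ancestral spectra plus per-subpopulation Balding-Nichols draws.

    Loci borrow the real kit names (so simulated files interoperate with
    the standard panels) and fall back to numbered names past the kit size.
    """
    from .markers import AUTOSOMAL_PANEL_21, X_PANEL_19

    kit = (X_PANEL_19 if linkage is Linkage.X_LINKED
           else tuple(m for m in AUTOSOMAL_PANEL_21 if m.is_str))
    names = [m.name for m in kit[:n_loci]]
    names += [f"{prefix}{i+1:02d}" for i in range(len(names), n_loci)]
    rng = config.substream(f"freqs:{prefix}")
    if linkage is Linkage.X_LINKED:
        lo, hi = config.alleles_min, config.alleles_max
    else:
        lo, hi = config.alleles_min_autosomal, config.alleles_max_autosomal
    loci = []
    for li in range(n_loci):
        k = int(rng.integers(lo, hi + 1))
        labels = _allele_labels(k, rng, config.microvariant_fraction)
        ancestral = rng.dirichlet(np.full(k, config.dirichlet_concentration))
        sub = {
            label: draw_subpop_frequencies(ancestral, F, rng)
            for label, _, F in config.subpopulations
        }
        loci.append((MarkerDef(names[li], linkage), labels, ancestral, sub))
    return loci


def _assemble(panel, rows) -> GenotypeTable:
    cols = ["SampleID", "Sex", "Population"]
    for m in panel:
        cols += [f"{m.name}_1", f"{m.name}_2"]
    return GenotypeTable(tuple(panel), pd.DataFrame(rows, columns=cols),
                         provenance="simulated")


def simulate_autosomal_table(config: SimConfig) -> GenotypeTable:
    """Study-shaped autosomal table: diploid HWE genotypes within each
    Balding-Nichols subpopulation, sexes assigned at the study's ratio."""
    config.validate()
    loci = _build_panel_frequencies(config, config.n_loci_autosomal, "AUT",
                                    Linkage.AUTOSOMAL)
    rng = config.substream("genotypes:aut")
    total = sum(s for _, s, _ in config.subpopulations)
    n_f = round(total * config.n_females_autosomal
                / (config.n_females_autosomal + config.n_males_autosomal))
    sexes = [Sex.FEMALE.value] * n_f + [Sex.MALE.value] * (total - n_f)
    rng.shuffle(sexes)
    rows = []
    i = 0
    for label, size, _ in config.subpopulations:
        calls_by_locus = {
            m.name: sample_genotypes(sub[label], labels, size, "diploid", rng)
            for m, labels, _, sub in loci
        }
        for s in range(size):
            row = {"SampleID": f"A{i+1:04d}", "Sex": sexes[i],
                   "Population": label}
            for m, _, _, _ in loci:
                a, b = calls_by_locus[m.name][s]
                row[f"{m.name}_1"], row[f"{m.name}_2"] = a, b
            rows.append(row)
            i += 1
    return _assemble([m for m, _, _, _ in loci], rows)


def simulate_x_table(config: SimConfig, *, with_dropout: bool = True
                     ) -> tuple[GenotypeTable, list[tuple[str, str]]]:
    """Sex-structured X table (females diploid, males hemizygous), with the
    configured male dropout rate injected when requested."""
    config.validate()
    loci = _build_panel_frequencies(config, config.n_loci_x, "XL",
                                    Linkage.X_LINKED)
    rng = config.substream("genotypes:x")
    total = config.n_females_x + config.n_males_x
    sizes = np.array([s for _, s, _ in config.subpopulations], dtype=float)
    pop_of = np.repeat([l for l, _, _ in config.subpopulations],
                       _proportional_counts(sizes, total))
    sexes = ([Sex.FEMALE.value] * config.n_females_x
             + [Sex.MALE.value] * config.n_males_x)
    rng.shuffle(sexes)
    rows = []
    for i in range(total):
        label = pop_of[i]
        row = {"SampleID": f"X{i+1:04d}", "Sex": sexes[i],
               "Population": label}
        for m, labels, _, sub in loci:
            p = sub[label]
            if sexes[i] == Sex.FEMALE.value:
                a, b = sample_genotypes(p, labels, 1, "diploid", rng)[0]
            else:
                a, b = sample_genotypes(p, labels, 1, "haploid", rng)[0]
            row[f"{m.name}_1"], row[f"{m.name}_2"] = a, b
        rows.append(row)
    table = _assemble([m for m, _, _, _ in loci], rows)
    injected: list[tuple[str, str]] = []
    if with_dropout and config.dropout_rate > 0:
        table, injected = inject_dropout(
            table, config.dropout_rate,
            int(config.substream("dropout").integers(2**31)))
    return table, injected


def _proportional_counts(sizes: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` across sizes."""
    quota = sizes / sizes.sum() * total
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quota - base))
    base[order[:rem]] += 1
    return base
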