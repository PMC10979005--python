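"""Core data model for STR genotype panels.

Alleles are opaque strings named by repeat count under the ISFG convention;
microvariants such as ``"9.3"`` are kept verbatim.  Sorting is numeric where
the label parses as a number ("9.3" falls between "9" and "10") and
lexicographic otherwise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Linkage",
    "Sex",
    "MarkerDef",
    "GenotypeTable",
    "AlleleFrequencySpectrum",
    "allele_sort_key",
    "normalize_allele",
    "estimate_frequencies",
    "count_distinct_alleles",
]


class Linkage(str, enum.Enum):
    AUTOSOMAL = "autosomal"
    X_LINKED = "x_linked"
    SEX_MARKER = "sex_marker"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


def normalize_allele(label: object) -> str:
    """Canonical string form of an allele designation.

    Trailing ``".0"`` produced by spreadsheet round-trips is stripped;
    microvariant decimals ("9.3") are preserved.
    """
    s = str(label).strip()
    if s.endswith(".0"):
        s = s[:-2]
    return s


def allele_sort_key(label: str):
    """Numeric-then-lexical ordering key for allele labels."""
    try:
        return (0, float(label), "")
    except ValueError:
        return (1, 0.0, label)


@dataclass(frozen=True)
class MarkerDef:
    """A locus in the typing panel.

    ``sex_marker`` loci (Amelogenin) are parsed but excluded from every STR
    statistic.
    """

    name: str
    linkage: Linkage = Linkage.AUTOSOMAL

    @property
    def is_str(self) -> bool:
        return self.linkage is not Linkage.SEX_MARKER


#: The 21-channel autosomal identification panel (20 STRs + Amelogenin).
AUTOSOMAL_PANEL_21: tuple[MarkerDef, ...] = tuple(
    MarkerDef(n, Linkage.SEX_MARKER if n == "AMEL" else Linkage.AUTOSOMAL)
    for n in (
        "D19S433", "D5S818", "D21S11", "D18S51", "D6S1043", "AMEL",
        "D3S1358", "D13S317", "D7S820", "D16S539", "CSF1PO", "PentaD",
        "D2S441", "vWA", "D8S1179", "TPOX", "PentaE", "TH01", "D12S391",
        "D2S1338", "FGA",
    )
)

#: The 19-locus X-chromosome panel.
X_PANEL_19: tuple[MarkerDef, ...] = tuple(
    MarkerDef(n, Linkage.X_LINKED)
    for n in (
        "DXS6795", "DXS6803", "DXS6807", "DXS9907", "DXS7423", "GATA172D05",
        "DXS101", "DXS9902", "DXS7133", "DXS6810", "GATA31E08", "DXS6800",
        "DXS981", "DXS10162", "DXS6809", "GATA165B12", "DXS10079",
        "DXS10135", "HPRTB", "DXS689", "DXS10146", "DXS10148",
    )[:19]
)


class SchemaError(ValueError):
    """Column/locus mismatch between a file and the declared panel."""


class ParseError(ValueError):
    """Malformed row or cell in a genotype file."""


class NoDataError(ValueError):
    """A stratum contains no usable calls."""


@dataclass
class GenotypeTable:
    """Per-individual allele calls for a panel of STR markers.

    The calls live in a pandas DataFrame with columns ``SampleID``, ``Sex``,
    ``Population`` and two columns ``<locus>_1`` / ``<locus>_2`` per locus.
    Missing calls are ``None``.  Males at X loci carry their single allele in
    ``<locus>_1`` with ``<locus>_2`` empty.
    """

    panel: tuple[MarkerDef, ...]
    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.panel = tuple(self.panel)
        names = [m.name for m in self.panel]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate locus names in panel")
        need = ["SampleID", "Sex", "Population"]
        for m in self.panel:
            need += [f"{m.name}_1", f"{m.name}_2"]
        missing = [c for c in need if c not in self.data.columns]
        if missing:
            raise SchemaError(f"table missing columns: {missing}")
        self.data = self.data.reset_index(drop=True)

    # -- convenience ------------------------------------------------------
    def marker(self, name: str) -> MarkerDef:
        for m in self.panel:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def str_markers(self) -> tuple[MarkerDef, ...]:
        return tuple(m for m in self.panel if m.is_str)

    @property
    def n_individuals(self) -> int:
        return len(self.data)

    def populations(self) -> list[str]:
        """Population labels in stable first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.data["Population"]:
            seen.setdefault(str(p), None)
        return list(seen)

    def subset(self, mask) -> "GenotypeTable":
        return GenotypeTable(self.panel, self.data.loc[mask].copy(),
                             self.provenance)

    def calls(self, locus: str) -> pd.DataFrame:
        """Two-column frame of calls at ``locus`` (None = missing)."""
        return self.data[[f"{locus}_1", f"{locus}_2"]]

    def genotype_counts(self, locus: str) -> dict[tuple[str, str], int]:
        """Observed diploid genotype counts (unordered pairs, sorted labels).

        Individuals with any missing call at the locus are skipped; for X
        loci this therefore uses females (and would silently skip males,
        whose second call is empty).
        """
        out: dict[tuple[str, str], int] = {}
        c1 = self.data[f"{locus}_1"]
        c2 = self.data[f"{locus}_2"]
        for a, b in zip(c1, c2):
            if _is_missing(a) or _is_missing(b):
                continue
            g = tuple(sorted((str(a), str(b)), key=allele_sort_key))
            out[g] = out.get(g, 0) + 1
        return out


def _is_missing(x: object) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x)) or x == ""


@dataclass(frozen=True)
class AlleleFrequencySpectrum:
    """Allele counts at one locus, with the chromosome total they came from.

    Counts are kept as exact integers; relative frequencies are derived
    views, so downstream products accumulate no rounding drift.
    """

    locus: str
    counts: Mapping[str, int]
    linkage: Linkage = Linkage.AUTOSOMAL

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts",
            dict(sorted(((str(k), int(v)) for k, v in self.counts.items()),
                        key=lambda kv: allele_sort_key(kv[0]))))
        if any(v <= 0 for v in self.counts.values()):
            raise ValueError("allele counts must be positive")
        if not self.counts:
            raise NoDataError(f"no alleles observed at {self.locus}")

    @property
    def n_chrom(self) -> int:
        return sum(self.counts.values())

    @property
    def alleles(self) -> list[str]:
        return list(self.counts)

    @property
    def freqs(self) -> np.ndarray:
        n = self.n_chrom
        return np.array([v / n for v in self.counts.values()])

    def freq(self, allele: str) -> float:
        return self.counts.get(str(allele), 0) / self.n_chrom

    def as_dict(self) -> dict[str, float]:
        n = self.n_chrom
        return {a: c / n for a, c in self.counts.items()}

    def __len__(self) -> int:
        return len(self.counts)


def _stratum_mask(table: GenotypeTable, stratum: str) -> pd.Series:
    sex = table.data["Sex"].astype(str)
    if stratum == "pooled":
        return pd.Series(True, index=table.data.index)
    if stratum == "females":
        return sex == Sex.FEMALE.value
    if stratum == "males":
        return sex == Sex.MALE.value
    raise ValueError(f"unknown stratum {stratum!r}")


def estimate_frequencies(
    table: GenotypeTable,
    locus: str | MarkerDef,
    stratum: str = "pooled",
) -> AlleleFrequencySpectrum:
    """Counting estimator of allele frequencies at one locus.

    For X-linked loci each female contributes 2 chromosomes and each male 1
    (his ``<locus>_1`` call); the pooled chromosome count is therefore
    ``2·F + M``.  Frequencies are counts divided by that total.

    Raises :class:`NoDataError` when the stratum holds no usable call —
    never silent zeros.
    """
    marker = table.marker(locus) if isinstance(locus, str) else locus
    mask = _stratum_mask(table, stratum)
    sub = table.data.loc[mask]
    counts: dict[str, int] = {}
    c1 = sub[f"{marker.name}_1"]
    c2 = sub[f"{marker.name}_2"]
    sexes = sub["Sex"].astype(str)
    for a, b, sx in zip(c1, c2, sexes):
        if marker.linkage is Linkage.X_LINKED and sx == Sex.MALE.value:
            if _is_missing(a):
                continue
            counts[str(a)] = counts.get(str(a), 0) + 1
        else:
            if _is_missing(a) or _is_missing(b):
                continue  # partial genotypes treated as missing locus
            for al in (a, b):
                counts[str(al)] = counts.get(str(al), 0) + 1
    if not counts:
        raise NoDataError(f"no data for {marker.name} in stratum {stratum!r}")
    return AlleleFrequencySpectrum(marker.name, counts, marker.linkage)


def estimate_frequencies_by_population(
    table: GenotypeTable, locus: str | MarkerDef
) -> dict[str, AlleleFrequencySpectrum]:
    out = {}
    for pop in table.populations():
        sub = table.subset(table.data["Population"].astype(str) == pop)
        try:
            out[pop] = estimate_frequencies(sub, locus)
        except NoDataError:
            continue
    return out


def count_distinct_alleles(
    spectra: Iterable[AlleleFrequencySpectrum],
) -> tuple[dict[str, int], int]:
    """Distinct alleles per locus and their panel-wide total."""
    per: dict[str, int] = {}
    for sp in spectra:
        per[sp.locus] = len(sp)
    return per, sum(per.values())
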