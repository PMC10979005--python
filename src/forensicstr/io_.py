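"""Reading and writing genotype tables and allele-frequency tables.

Genotype files are delimited text, one row per individual, with columns
``SampleID, Sex, Population`` followed by allele columns.  Autosomal loci use
two columns ``LOCUS_1, LOCUS_2``; X loci may use one or two (a male's single
call may sit in a lone ``LOCUS`` column or in ``LOCUS_1``).  Missing calls
are empty cells (sentinel configurable).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .markers import (
    AlleleFrequencySpectrum,
    GenotypeTable,
    Linkage,
    MarkerDef,
    ParseError,
    SchemaError,
    Sex,
    allele_sort_key,
    normalize_allele,
)

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "validate_x_males",
    "XValidationReport",
    "write_frequency_table",
    "read_frequency_table",
]

_SEX_ALIASES = {
    "f": Sex.FEMALE, "female": Sex.FEMALE, "xx": Sex.FEMALE,
    "m": Sex.MALE, "male": Sex.MALE, "xy": Sex.MALE,
    "": Sex.UNKNOWN, "u": Sex.UNKNOWN, "unknown": Sex.UNKNOWN,
}


def _parse_sex(raw: object, line: int) -> str:
    s = str(raw).strip().lower()
    if s in _SEX_ALIASES:
        return _SEX_ALIASES[s].value
    raise ParseError(f"line {line}: unrecognized sex {raw!r}")


def read_genotype_table(
    path: str | Path,
    panel: Sequence[MarkerDef],
    *,
    sep: str = "\t",
    missing: str = "",
) -> GenotypeTable:
    """Read a delimited genotype file against a declared panel.

    Unknown locus columns raise :class:`SchemaError`; malformed cells raise
    :class:`ParseError` naming the offending line.  Allele strings are
    normalized (trailing ``.0`` stripped, microvariants verbatim).  A male
    with two identical X calls is collapsed to one; two *distinct* X calls
    are kept verbatim so :func:`validate_x_males` can report them.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    by_name = {m.name: m for m in panel}
    meta = {"SampleID", "Sex", "Population"}
    present: set[str] = set()
    for col in raw.columns:
        if col in meta:
            continue
        base = col[:-2] if col.endswith(("_1", "_2")) else col
        if base not in by_name:
            raise SchemaError(f"unknown locus column {col!r}")
        present.add(base)
    for col in ("SampleID", "Sex", "Population"):
        if col not in raw.columns:
            raise SchemaError(f"missing required column {col!r}")
    # the declared panel is a superset; the table carries the loci typed
    panel = [m for m in panel if m.name in present]
    if not panel:
        raise SchemaError("no panel locus columns found in file")

    rows = []
    for i, rec in raw.iterrows():
        line = i + 2  # 1-based, after header
        out = {
            "SampleID": str(rec["SampleID"]).strip(),
            "Sex": _parse_sex(rec["Sex"], line),
            "Population": str(rec["Population"]).strip(),
        }
        if not out["SampleID"]:
            raise ParseError(f"line {line}: empty SampleID")
        for m in panel:
            vals = []
            for col in (f"{m.name}_1", f"{m.name}_2", m.name):
                if col in raw.columns:
                    v = str(rec[col]).strip()
                    vals.append(None if v == missing else normalize_allele(v))
            # a lone "LOCUS" column contributes one call
            a = vals[0] if vals else None
            b = vals[1] if len(vals) > 1 else None
            if m.linkage is Linkage.X_LINKED and out["Sex"] == Sex.MALE.value:
                if a is None and b is not None:
                    a, b = b, None
                if a is not None and b == a:
                    b = None  # homozygous-looking male call = one chromosome
            elif m.linkage is Linkage.AUTOSOMAL or m.linkage is Linkage.SEX_MARKER:
                if (a is None) != (b is None):
                    # partial genotype: treated as missing locus
                    a = b = None
            out[f"{m.name}_1"] = a
            out[f"{m.name}_2"] = b
        rows.append(out)

    cols = ["SampleID", "Sex", "Population"]
    for m in panel:
        cols += [f"{m.name}_1", f"{m.name}_2"]
    df = pd.DataFrame(rows, columns=cols)
    return GenotypeTable(tuple(panel), df, provenance=f"read from {path}")


def write_genotype_table(table: GenotypeTable, path: str | Path,
                         *, sep: str = "\t", missing: str = "") -> None:
    df = table.data.copy()
    df = df.where(df.notna(), missing)
    df = df.replace({None: missing})
    df.to_csv(path, sep=sep, index=False)


@dataclasses.dataclass
class XValidationReport:
    """What :func:`validate_x_males` removed and why."""

    removed_samples: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    removed_calls: list[tuple[str, str, str]] = dataclasses.field(default_factory=list)

    @property
    def n_removed_samples(self) -> int:
        return len(self.removed_samples)

    def __bool__(self) -> bool:
        return bool(self.removed_samples or self.removed_calls)


def validate_x_males(
    table: GenotypeTable,
    policy: str = "exclude_sample",
) -> tuple[GenotypeTable, XValidationReport]:
    """Screen male X calls for dropout and heterozygous (two-allele) calls.

    Policies:

    ``exclude_sample`` (default)
        a male with any X-locus dropout or two distinct X alleles is removed
        entirely — the handling applied to the two dropout males in the
        source study.
    ``exclude_locus_call``
        only the offending call is blanked; the sample is kept.
    ``error``
        raise on the first violation.
    """
    if policy not in {"exclude_sample", "exclude_locus_call", "error"}:
        raise ValueError(f"unknown policy {policy!r}")
    x_loci = [m for m in table.panel if m.linkage is Linkage.X_LINKED]
    report = XValidationReport()
    df = table.data.copy()
    drop_rows: list[int] = []
    males = df["Sex"].astype(str) == Sex.MALE.value
    for idx in df.index[males]:
        sid = df.at[idx, "SampleID"]
        for m in x_loci:
            a = df.at[idx, f"{m.name}_1"]
            b = df.at[idx, f"{m.name}_2"]
            a_missing = a is None or a == "" or (isinstance(a, float) and np.isnan(a))
            b_present = b is not None and b != "" and not (
                isinstance(b, float) and np.isnan(b))
            if a_missing and not b_present:
                reason = f"dropout at {m.name}"
            elif b_present:
                reason = f"two distinct X alleles at {m.name}"
            else:
                continue
            if policy == "error":
                raise ValueError(f"sample {sid}: {reason}")
            if policy == "exclude_sample":
                report.removed_samples.append((str(sid), reason))
                drop_rows.append(idx)
                break
            report.removed_calls.append((str(sid), m.name, reason))
            df.at[idx, f"{m.name}_1"] = None
            df.at[idx, f"{m.name}_2"] = None
    if drop_rows:
        df = df.drop(index=drop_rows)
    return GenotypeTable(table.panel, df, table.provenance), report


def write_frequency_table(
    spectra: Iterable[AlleleFrequencySpectrum],
    path: str | Path,
) -> None:
    """Locus × allele frequency matrix, 4-decimal display, lossless counts.

    Layout: rows are alleles (union over loci, numeric order), columns are
    loci; each cell holds ``frequency`` to 4 decimals or empty.  Below the
    frequency block a ``n_chrom`` row gives the chromosome totals and one
    ``count:<allele>`` row per allele row restores the exact integer counts,
    so read∘write is the identity on counts.
    """
    spectra = list(spectra)
    loci = [sp.locus for sp in spectra]
    alleles = sorted({a for sp in spectra for a in sp.alleles},
                     key=allele_sort_key)
    rows = []
    for a in alleles:
        rows.append([a] + [
            f"{sp.counts[a] / sp.n_chrom:.4f}" if a in sp.counts else ""
            for sp in spectra
        ])
    rows.append(["n_chrom"] + [str(sp.n_chrom) for sp in spectra])
    for a in alleles:
        rows.append([f"count:{a}"] + [
            str(sp.counts[a]) if a in sp.counts else "" for sp in spectra
        ])
    pd.DataFrame(rows, columns=["Allele"] + loci).to_csv(path, index=False)


def read_frequency_table(path: str | Path) -> list[AlleleFrequencySpectrum]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    loci = [c for c in df.columns if c != "Allele"]
    counts: dict[str, dict[str, int]] = {l: {} for l in loci}
    for _, rec in df.iterrows():
        key = rec["Allele"]
        if key.startswith("count:"):
            allele = key[len("count:"):]
            for l in loci:
                if rec[l] != "":
                    counts[l][allele] = int(rec[l])
    return [AlleleFrequencySpectrum(l, c) for l, c in counts.items() if c]
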