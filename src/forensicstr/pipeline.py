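"""End-to-end analysis pipelines over a genotype table.

Each pipeline is a pure function of (input table, config): seeded
throughout, it writes machine-readable CSV/JSON into an output directory
together with the serialized config, and logs the sample counts at every
filtering step.  Display rounding: frequencies and per-locus parameters at
4 decimals, combined values at 15 significant digits (their complements
from 1 carry the information).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import exact_tests, forensic, io_, structure, xstr
from .markers import (
    GenotypeTable,
    Linkage,
    NoDataError,
    Sex,
    count_distinct_alleles,
    estimate_frequencies,
    estimate_frequencies_by_population,
)

__all__ = ["RunConfig", "run_autosomal_pipeline", "run_x_pipeline"]

log = logging.getLogger("forensicstr")


@dataclasses.dataclass
class RunConfig:
    """Pipeline thresholds and seeds; serialized into every output dir."""

    alpha: float = 0.05
    grouping_threshold: int = 10
    dropout_policy: str = "exclude_sample"
    seed: int = 0
    hwe_max_tables: int = 100_000
    hwe_n_steps: int = 200_000
    hwe_burn_in: int = 20_000
    ld_max_tables: int = 50_000
    ld_n_permutations: int = 2_000
    ld_genotypic_permutations: int = 500
    fst_min_size: int = 2
    run_structure: bool = True
    run_ld: bool = True

    def dump(self, outdir: Path) -> None:
        (outdir / "run_config.json").write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _round_stats_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    for c in df.columns:
        if df[c].dtype == float:
            df[c] = df[c].round(4)
    return df


def _fmt15(x: float) -> float:
    return float(f"{x:.15g}")


def run_autosomal_pipeline(table: GenotypeTable, config: RunConfig,
                           outdir: str | Path) -> dict:
    """Frequencies, forensic parameters, HWE, combined values and (given
    ≥2 populations) structure outputs for an autosomal table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.dump(outdir)
    loci = [m for m in table.str_markers if m.linkage is Linkage.AUTOSOMAL]
    log.info("autosomal pipeline: %d individuals, %d STR loci",
             table.n_individuals, len(loci))

    spectra = [estimate_frequencies(table, m) for m in loci]
    io_.write_frequency_table(spectra, outdir / "allele_frequencies.csv")
    per_locus, total_alleles = count_distinct_alleles(spectra)

    stats = []
    hwe_rows = []
    for m, sp in zip(loci, spectra):
        gc = table.genotype_counts(m.name)
        stats.append(forensic.locus_stats(gc, sp, warn_small=False))
        res = exact_tests.hwe_exact_test(
            gc, max_tables=config.hwe_max_tables,
            n_steps=config.hwe_n_steps, burn_in=config.hwe_burn_in,
            seed=config.seed, locus=m.name)
        hwe_rows.append({"locus": m.name, "p_value": res.p_value,
                         "method": res.method, "se": res.standard_error})
    _round_stats_frame([s.as_dict() for s in stats]).to_csv(
        outdir / "forensic_parameters.csv", index=False)

    thr, decisions = exact_tests.bonferroni(
        [r["p_value"] for r in hwe_rows], config.alpha)
    for r, d in zip(hwe_rows, decisions):
        r["significant_after_bonferroni"] = bool(d)
    hdf = pd.DataFrame(hwe_rows)
    hdf.to_csv(outdir / "hwe_tests.csv", index=False)

    combined = forensic.combine(stats)
    summary = {
        "n_individuals": table.n_individuals,
        "n_loci": len(loci),
        "total_distinct_alleles": total_alleles,
        "CMP": _fmt15(combined.CMP),
        "CPD": _fmt15(combined.CPD),
        "CPE_trio": _fmt15(combined.CPE_trio),
        "CPE_duo": _fmt15(combined.CPE_duo),
        "hwe_bonferroni_threshold": thr,
        "hwe_significant_loci": [r["locus"] for r in hwe_rows
                                 if r["significant_after_bonferroni"]],
    }

    grouped = structure.group_small_populations(
        table, config.grouping_threshold)
    if config.run_structure and len(grouped.populations()) >= 2:
        fst_dm, _ = structure.pairwise_fst(
            grouped, loci=[m.name for m in loci],
            min_size=config.fst_min_size, seed=config.seed)
        fst_dm.to_csv(outdir / "pairwise_fst.csv")
        pop_freqs = {}
        for pop in grouped.populations():
            sub = grouped.subset(
                grouped.data["Population"].astype(str) == pop)
            freqs = {}
            for m in loci:
                try:
                    freqs[m.name] = estimate_frequencies(sub, m)
                except NoDataError:
                    continue
            pop_freqs[pop] = freqs
        nei_dm = structure.nei_distance_matrix(pop_freqs)
        nei_dm.to_csv(outdir / "nei_distances.csv")
        finite = fst_dm.clamped()
        if len(finite.labels) >= 3:
            (outdir / "nj_tree_fst.nwk").write_text(
                structure.neighbor_joining(finite) + "\n")
            structure.mds_coordinates_frame(nei_dm).to_csv(
                outdir / "mds_nei.csv")
        summary["populations"] = grouped.populations()
    else:
        log.info("structure stage skipped: fewer than two populations "
                 "after grouping")
        summary["structure_skipped"] = "fewer than two populations"

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    return summary


def run_x_pipeline(table: GenotypeTable, config: RunConfig,
                   outdir: str | Path) -> dict:
    """X-STR pipeline: dropout policy, three frequency strata, per-locus X
    parameters, female HWE, male haploid LD, female genotypic LD, combined
    values."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.dump(outdir)
    loci = [m for m in table.panel if m.linkage is Linkage.X_LINKED]
    n0 = table.n_individuals
    table, report = io_.validate_x_males(table, config.dropout_policy)
    log.info("x pipeline: %d individuals (%d removed by %s), %d loci",
             table.n_individuals, n0 - table.n_individuals,
             config.dropout_policy, len(loci))
    sexes = table.data["Sex"].astype(str)
    n_f = int((sexes == Sex.FEMALE.value).sum())
    n_m = int((sexes == Sex.MALE.value).sum())

    for stratum in ("pooled", "females", "males"):
        sp = []
        for m in loci:
            try:
                sp.append(estimate_frequencies(table, m, stratum))
            except NoDataError:
                continue
        io_.write_frequency_table(sp, outdir / f"x_frequencies_{stratum}.csv")

    pooled = {m.name: estimate_frequencies(table, m) for m in loci}
    xstats = []
    hwe_rows = []
    for m in loci:
        fem_gc = table.genotype_counts(m.name)  # only females have 2 calls
        xstats.append(xstr.x_locus_stats(pooled[m.name], fem_gc))
        res = exact_tests.hwe_exact_test(
            fem_gc, max_tables=config.hwe_max_tables,
            n_steps=config.hwe_n_steps, burn_in=config.hwe_burn_in,
            seed=config.seed, locus=m.name)
        hwe_rows.append({"locus": m.name, "p_value": res.p_value,
                         "method": res.method, "se": res.standard_error})
    _round_stats_frame([s.as_dict() for s in xstats]).to_csv(
        outdir / "x_forensic_parameters.csv", index=False)
    thr, decisions = exact_tests.bonferroni(
        [r["p_value"] for r in hwe_rows], config.alpha)
    for r, d in zip(hwe_rows, decisions):
        r["significant_after_bonferroni"] = bool(d)
    pd.DataFrame(hwe_rows).to_csv(outdir / "x_hwe_female.csv", index=False)

    summary = {
        "n_individuals": table.n_individuals,
        "n_females": n_f,
        "n_males": n_m,
        "n_removed_samples": report.n_removed_samples,
        "n_loci": len(loci),
        "hwe_bonferroni_threshold": thr,
    }
    combined = xstr.combine_x(xstats)
    summary.update({k: _fmt15(v) for k, v in combined.items()})

    # male haplotype diversity over the full profiles
    male_rows = table.data.loc[sexes == Sex.MALE.value]
    haps = []
    for _, rec in male_rows.iterrows():
        prof = tuple(rec[f"{m.name}_1"] for m in loci)
        if None not in prof:
            haps.append(prof)
    if len(haps) >= 2:
        summary["male_haplotype_diversity"] = _fmt15(
            xstr.haplotype_diversity(haps))

    if config.run_ld:
        pairs = exact_tests.pair_enumeration([m.name for m in loci])
        summary["n_locus_pairs"] = len(pairs)
        if n_m >= 2:
            rows = []
            for la, lb in pairs:
                hp = [(a, b) for a, b in zip(
                    male_rows[f"{la}_1"], male_rows[f"{lb}_1"])
                    if a is not None and b is not None]
                res = exact_tests.ld_exact_test_haploid(
                    hp, max_tables=config.ld_max_tables,
                    n_permutations=config.ld_n_permutations,
                    seed=config.seed, loci=(la, lb))
                rows.append({"locus_a": la, "locus_b": lb,
                             "p_value": res.p_value, "method": res.method})
            thr_ld, dec = exact_tests.bonferroni(
                [r["p_value"] for r in rows], config.alpha)
            for r, d in zip(rows, dec):
                r["significant_after_bonferroni"] = bool(d)
            pd.DataFrame(rows).to_csv(outdir / "x_ld_male.csv", index=False)
            summary["ld_male_bonferroni_threshold"] = thr_ld
        else:
            log.info("male LD stage skipped: fewer than two males")
            summary["ld_male_skipped"] = "fewer than two males"
        if n_f >= 2:
            fem_rows = table.data.loc[sexes == Sex.FEMALE.value]
            rows = []
            for la, lb in pairs:
                gp = []
                for _, rec in fem_rows.iterrows():
                    g1 = (rec[f"{la}_1"], rec[f"{la}_2"])
                    g2 = (rec[f"{lb}_1"], rec[f"{lb}_2"])
                    if None not in g1 and None not in g2:
                        gp.append((g1, g2))
                res = exact_tests.ld_test_genotypic(
                    gp, n_permutations=config.ld_genotypic_permutations,
                    seed=config.seed, loci=(la, lb))
                rows.append({"locus_a": la, "locus_b": lb,
                             "p_value": res.p_value, "method": res.method})
            thr_ld, dec = exact_tests.bonferroni(
                [r["p_value"] for r in rows], config.alpha)
            for r, d in zip(rows, dec):
                r["significant_after_bonferroni"] = bool(d)
            pd.DataFrame(rows).to_csv(outdir / "x_ld_female.csv",
                                      index=False)
            summary["ld_female_bonferroni_threshold"] = thr_ld
        else:
            log.info("female LD stage skipped: fewer than two females")
            summary["ld_female_skipped"] = "fewer than two females"

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    return summary
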