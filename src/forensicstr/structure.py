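"""Between-population differentiation and its standard visual summaries.

* Weir-Cockerham θ (variance-component FST), averaged over loci and
  alleles, with an optional permutation p-value.
* Nei's (1972) standard genetic distance, identities averaged over loci
  before the log-ratio.
* Classical (Torgerson) multidimensional scaling of a distance matrix.
* Neighbor-joining trees (via scikit-bio) with Newick output.

Negative θ estimates are a known property of the estimator in weakly
differentiated samples and are reported unclamped; a clamped view is
available for tree/ordination input.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .markers import (
    AlleleFrequencySpectrum,
    GenotypeTable,
    Linkage,
    estimate_frequencies,
)

__all__ = [
    "DistanceMatrix",
    "weir_cockerham_theta",
    "pairwise_fst",
    "nei_standard_distance",
    "nei_distance_matrix",
    "classical_mds",
    "neighbor_joining",
    "group_small_populations",
]


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix (FST or Nei D)."""

    labels: list[str]
    values: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("matrix not symmetric")
        np.fill_diagonal(v, 0.0)
        self.values = v

    def clamped(self) -> "DistanceMatrix":
        """Negative entries (possible for the θ estimator) set to zero."""
        return DistanceMatrix(list(self.labels),
                              np.clip(self.values, 0.0, None),
                              self.metric_name + "_clamped")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels,
                     columns=self.labels).to_csv(path)

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab[:10].ljust(10) + " "
                         + " ".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _locus_pop_summaries(tables: Sequence[GenotypeTable], locus: str):
    """Per-population (n_i, allele freq vector, het freq vector) at a locus."""
    alleles: list[str] = []
    for t in tables:
        for a in t.genotype_counts(locus):
            for al in a:
                if al not in alleles:
                    alleles.append(al)
    alleles = sorted(alleles)
    ai = {a: i for i, a in enumerate(alleles)}
    out = []
    for t in tables:
        gc = t.genotype_counts(locus)
        n = sum(gc.values())
        if n == 0:
            out.append((0, None, None))
            continue
        p = np.zeros(len(alleles))
        h = np.zeros(len(alleles))
        for (a, b), c in gc.items():
            p[ai[a]] += c
            p[ai[b]] += c
            if a != b:
                h[ai[a]] += c
                h[ai[b]] += c
        p /= 2 * n
        h /= n
        out.append((n, p, h))
    return out


def weir_cockerham_theta(
    tables: Sequence[GenotypeTable],
    loci: Sequence[str] | None = None,
) -> float:
    """Multi-locus Weir-Cockerham θ between ≥2 population samples.

    Variance components a (between populations), b (between individuals
    within populations) and c (within individuals) are accumulated over
    every allele of every locus; θ = Σa / Σ(a+b+c).
    """
    if len(tables) < 2:
        raise ValueError("need at least two populations")
    if loci is None:
        loci = [m.name for m in tables[0].str_markers
                if m.linkage is Linkage.AUTOSOMAL]
    num = 0.0
    den = 0.0
    for locus in loci:
        summ = [s for s in _locus_pop_summaries(tables, locus) if s[0] >= 1]
        r = len(summ)
        if r < 2:
            continue
        ns = np.array([s[0] for s in summ], dtype=float)
        nbar = ns.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
        k = len(summ[0][1])
        for a_idx in range(k):
            ps = np.array([s[1][a_idx] for s in summ])
            hs = np.array([s[2][a_idx] for s in summ])
            pbar = (ns * ps).sum() / (r * nbar)
            s2 = (ns * (ps - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (ns * hs).sum() / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                / (nbar - 1))
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            num += a
            den += a + b + c
    if den == 0.0:
        return 0.0
    return num / den


def pairwise_fst(
    table: GenotypeTable,
    *,
    loci: Sequence[str] | None = None,
    min_size: int = 2,
    n_permutations: int = 0,
    seed: int | None = None,
) -> tuple[DistanceMatrix, pd.DataFrame | None]:
    """Pairwise Weir-Cockerham θ between all population labels of a table.

    Populations below ``min_size`` individuals get NaN rows with a warning.
    With ``n_permutations`` > 0, a one-sided permutation p-value (individuals
    shuffled between the two groups) is returned alongside.
    """
    pops = table.populations()
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    subs = {p: table.subset(table.data["Population"].astype(str) == p)
            for p in pops}
    small = [p for p in pops if subs[p].n_individuals < min_size]
    if small:
        warnings.warn(f"populations below min_size={min_size}: {small}",
                      stacklevel=2)
    k = len(pops)
    vals = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            if pops[i] in small or pops[j] in small:
                vals[i, j] = vals[j, i] = np.nan
                continue
            theta = weir_cockerham_theta([subs[pops[i]], subs[pops[j]]], loci)
            vals[i, j] = vals[j, i] = theta
            if n_permutations:
                merged = pd.concat(
                    [subs[pops[i]].data, subs[pops[j]].data],
                    ignore_index=True)
                ni = subs[pops[i]].n_individuals
                hits = 0
                for _ in range(n_permutations):
                    perm = rng.permutation(len(merged))
                    ga = GenotypeTable(table.panel,
                                       merged.iloc[perm[:ni]].copy())
                    gb = GenotypeTable(table.panel,
                                       merged.iloc[perm[ni:]].copy())
                    if weir_cockerham_theta([ga, gb], loci) >= theta:
                        hits += 1
                pvals[i, j] = pvals[j, i] = (hits + 1) / (n_permutations + 1)
    dm = DistanceMatrix(pops, vals, "weir_cockerham_fst")
    pdf = (pd.DataFrame(pvals, index=pops, columns=pops)
           if n_permutations else None)
    return dm, pdf


# ---------------------------------------------------------------------------
# Nei standard distance
# ---------------------------------------------------------------------------

def nei_standard_distance(
    freqs_a: Mapping[str, AlleleFrequencySpectrum],
    freqs_b: Mapping[str, AlleleFrequencySpectrum],
) -> float:
    """Nei (1972) standard distance D = -ln( Jxy / sqrt(Jx·Jy) ).

    Identities Jxy, Jx, Jy are averaged over the shared loci before the
    ratio.  Loci present on only one side are dropped with a warning.
    Disjoint allele sets give Jxy = 0 and D = +inf.
    """
    shared = [l for l in freqs_a if l in freqs_b]
    dropped = set(freqs_a) ^ set(freqs_b)
    if dropped:
        warnings.warn(f"loci missing on one side dropped: {sorted(dropped)}",
                      stacklevel=2)
    if not shared:
        raise ValueError("no shared loci")
    jxy = jx = jy = 0.0
    for l in shared:
        da = freqs_a[l].as_dict()
        db = freqs_b[l].as_dict()
        jxy += sum(da[a] * db.get(a, 0.0) for a in da)
        jx += sum(v * v for v in da.values())
        jy += sum(v * v for v in db.values())
    L = len(shared)
    jxy /= L
    jx /= L
    jy /= L
    if jxy == 0.0:
        return math.inf
    return -math.log(jxy / math.sqrt(jx * jy))


def nei_distance_matrix(
    pop_freqs: Mapping[str, Mapping[str, AlleleFrequencySpectrum]],
) -> DistanceMatrix:
    pops = list(pop_freqs)
    k = len(pops)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = nei_standard_distance(pop_freqs[pops[i]], pop_freqs[pops[j]])
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(pops, vals, "nei_1972")


# ---------------------------------------------------------------------------
# Classical MDS (principal coordinates)
# ---------------------------------------------------------------------------

def classical_mds(dm: DistanceMatrix, k: int = 2
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson/Gower scaling: double-center -D²/2, eigendecompose, embed.

    Returns (coordinates n×k', eigenvalues descending, all of them including
    negative ones).  ``k`` is reduced with a warning when fewer than ``k``
    positive eigenvalues exist.  Coordinates are identified only up to
    rotation/reflection; compare reconstructed distances, not raw axes.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least three populations")
    D2 = np.asarray(dm.values, dtype=float) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    n_pos = int((evals > 1e-12 * max(1.0, abs(evals[0]))).sum())
    if k > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; reducing k from {k}",
                      stacklevel=2)
        k = n_pos
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    return coords, evals


def mds_coordinates_frame(dm: DistanceMatrix, k: int = 2) -> pd.DataFrame:
    coords, evals = classical_mds(dm, k)
    df = pd.DataFrame(coords, index=dm.labels,
                      columns=[f"axis{i+1}" for i in range(coords.shape[1])])
    df.attrs["eigenvalues"] = evals.tolist()
    df.attrs["note"] = "sign/rotation arbitrary"
    return df


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns the unrooted tree as Newick.

    Infinite distances are rejected with instructions to cap them first.
    """
    if len(dm.labels) < 3:
        raise ValueError("need at least three labels")
    if not np.all(np.isfinite(dm.values)):
        raise ValueError(
            "distance matrix holds infinite entries; cap them (e.g. at the "
            "largest finite distance) before tree building")
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj

    tree = nj(SkDM(dm.values, ids=dm.labels))
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def tree_tip_distances(newick: str) -> DistanceMatrix:
    """Path-length distances between all leaf pairs of a Newick tree."""
    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(newick))
    skdm = tree.tip_tip_distances()
    labels = list(skdm.ids)
    return DistanceMatrix(labels, np.asarray(skdm.data), "tree_path_length")


# ---------------------------------------------------------------------------
# Small-group pooling
# ---------------------------------------------------------------------------

def group_small_populations(table: GenotypeTable, threshold: int = 10,
                            label: str = "Other") -> GenotypeTable:
    """Relabel populations below ``threshold`` individuals as ``label``.

    Mirrors the practice of pooling small ethnic samples before structure
    analyses; the threshold is deliberately a parameter.
    """
    sizes = table.data["Population"].astype(str).value_counts()
    small = set(sizes[sizes < threshold].index)
    df = table.data.copy()
    df["Population"] = [label if str(p) in small else str(p)
                        for p in df["Population"]]
    return GenotypeTable(table.panel, df, table.provenance)
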