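"""Exact tests of Hardy-Weinberg equilibrium and linkage disequilibrium.

All tests are conditional exact tests under the probability ordering: the
p-value is the null probability of outcomes no more probable than the one
observed, conditioning on the observed allele (or margin) counts.  Small
state spaces are fully enumerated; larger ones fall back to seeded Monte
Carlo, reported with a standard error.

HWE null distribution given allele counts is the random-pairing law

    P(table) = n! 2^h Π a_i! / ( (2n)! Π n_ij! ),   h = # heterozygotes,

sampled either by a Markov chain of random transpositions of the gene-copy
vector (the Guo-Thompson approach; default beyond the enumeration bound) or
by i.i.d. random pairings ("permutation" method, exact binomial SE).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .markers import allele_sort_key

__all__ = [
    "TestResult",
    "hwe_exact_test",
    "ld_exact_test_haploid",
    "ld_test_genotypic",
    "bonferroni",
    "pair_enumeration",
]

_TIE_TOL = 1e-9


@dataclass(frozen=True)
class TestResult:
    test_name: str
    locus: str | tuple[str, str]
    p_value: float
    method: str  # full_enumeration | markov_chain | permutation | likelihood_ratio_em | degenerate
    n_steps: int = 0
    seed: int | None = None
    standard_error: float | None = None
    statistic: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0,1]")


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

def _table_from_counts(genotype_counts: Mapping[tuple, int]):
    alleles = sorted({a for g in genotype_counts for a in g},
                     key=lambda x: allele_sort_key(str(x)))
    idx = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    tab = np.zeros((k, k), dtype=np.int64)  # lower triangle i >= j
    for (a, b), c in genotype_counts.items():
        i, j = sorted((idx[a], idx[b]), reverse=True)
        tab[i, j] += c
    return alleles, tab


def _hwe_log_stat(tab: np.ndarray) -> float:
    """h·ln2 - Σ ln n_ij! — the table-dependent part of ln P(table)."""
    k = tab.shape[0]
    het = int(tab.sum() - np.trace(tab))
    return het * math.log(2.0) - float(
        gammaln(tab[np.tril_indices(k)] + 1).sum())


class EnumerationTooLarge(RuntimeError):
    pass


def _hwe_enumeration_p(tab: np.ndarray, max_tables: int) -> float:
    """Depth-first enumeration of every genotype table with the observed
    allele margins, accumulating the probability-ordering p-value.

    The statistic h·ln2 - Σ ln n_ij! is built up incrementally during the
    recursion, so each leaf costs O(1) beyond the tree walk.
    """
    k = tab.shape[0]
    if k > 12:
        raise EnumerationTooLarge  # recursion depth/space hopeless
    a = (tab.sum(axis=0) + tab.sum(axis=1)).astype(np.int64)
    n = int(tab.sum())
    log_const = float(gammaln(n + 1) + gammaln(a + 1).sum()
                      - gammaln(2 * n + 1))
    t_obs = _hwe_log_stat(tab)
    cut = t_obs + _TIE_TOL * (1.0 + abs(t_obs))
    lgf = gammaln(np.arange(n + 2) + 1.0)  # ln m!
    ln2 = math.log(2.0)
    node_budget = 40 * max_tables  # bounds tree-walk time, not just leaves
    acc = {"p": 0.0, "total": 0.0, "seen": 0, "nodes": 0}
    rem = a.copy()

    def fill_row(i: int, stat: float):
        if i == k:
            acc["seen"] += 1
            if acc["seen"] > max_tables:
                raise EnumerationTooLarge
            prob = math.exp(log_const + stat)
            acc["total"] += prob
            if stat <= cut:
                acc["p"] += prob
            return
        ri = int(rem[i])
        for n_ii in range(ri // 2 + 1):
            fill_cells(i, i + 1, ri - 2 * n_ii, stat - lgf[n_ii])

    def fill_cells(i: int, j: int, left: int, stat: float):
        acc["nodes"] += 1
        if acc["nodes"] > node_budget:
            raise EnumerationTooLarge
        if j == k:
            if left == 0:
                fill_row(i + 1, stat)
            return
        hi = min(left, int(rem[j]))
        lo = max(0, left - int(rem[j + 1:].sum()))
        for n_ij in range(lo, hi + 1):
            rem[j] -= n_ij
            fill_cells(i, j + 1, left - n_ij,
                       stat + n_ij * ln2 - lgf[n_ij])
            rem[j] += n_ij

    fill_row(0, 0.0)
    # normalization guard: enumeration must account for all mass
    if abs(acc["total"] - 1.0) > 1e-8:
        raise RuntimeError(f"enumeration mass {acc['total']} != 1")
    return min(acc["p"], 1.0)


def _copies_vector(tab: np.ndarray) -> np.ndarray:
    """Gene copies laid out so consecutive entries pair into the observed
    genotypes."""
    out = []
    k = tab.shape[0]
    for i in range(k):
        for j in range(i + 1):
            out += [i, j] * int(tab[i, j])
    return np.array(out, dtype=np.int64)


def _hwe_chain_p(tab: np.ndarray, n_steps: int, burn_in: int,
                 rng: np.random.Generator) -> tuple[float, float]:
    """Transposition Markov chain over gene-copy arrangements; stationary
    law is the random-pairing null.  Returns (p, batch-means SE)."""
    k = tab.shape[0]
    v = _copies_vector(tab)
    m = len(v)
    cur = tab.astype(np.int64).copy()  # lower triangle
    t_obs = _hwe_log_stat(tab)
    cut = t_obs + _TIE_TOL * (1.0 + abs(t_obs))
    t_cur = t_obs

    lg = gammaln(np.arange(int(tab.sum()) + 2) + 1.0)
    ln2 = math.log(2.0)

    def cell_stat(i, j, n):
        return (ln2 * n if i != j else 0.0) - lg[n]

    us = rng.integers(0, m, size=n_steps)
    ws = rng.integers(0, m, size=n_steps)
    hits = np.empty(n_steps - burn_in, dtype=np.bool_)
    for step in range(n_steps):
        u = us[step]
        w = ws[step]
        pu, pw = u // 2, w // 2
        if pu != pw and v[u] != v[w]:
            # affected pairs
            au, bu = v[2 * pu], v[2 * pu + 1]
            aw, bw = v[2 * pw], v[2 * pw + 1]
            cells = []
            for (x, y) in ((au, bu), (aw, bw)):
                i, j = (x, y) if x >= y else (y, x)
                cells.append((i, j))
            # perform swap
            v[u], v[w] = v[w], v[u]
            au2, bu2 = v[2 * pu], v[2 * pu + 1]
            aw2, bw2 = v[2 * pw], v[2 * pw + 1]
            new_cells = []
            for (x, y) in ((au2, bu2), (aw2, bw2)):
                i, j = (x, y) if x >= y else (y, x)
                new_cells.append((i, j))
            delta = 0.0
            for (i, j) in cells:
                n0 = cur[i, j]
                delta -= cell_stat(i, j, n0)
                cur[i, j] = n0 - 1
                delta += cell_stat(i, j, n0 - 1)
            for (i, j) in new_cells:
                n0 = cur[i, j]
                delta -= cell_stat(i, j, n0)
                cur[i, j] = n0 + 1
                delta += cell_stat(i, j, n0 + 1)
            t_cur += delta
        if step >= burn_in:
            hits[step - burn_in] = t_cur <= cut
    p = float(hits.mean())
    # batch-means SE for the correlated chain
    nb = min(100, len(hits))
    usable = (len(hits) // nb) * nb
    batches = hits[:usable].reshape(nb, -1).mean(axis=1)
    se = float(batches.std(ddof=1) / math.sqrt(nb)) if nb > 1 else float("nan")
    return p, se


def _hwe_pairing_p(tab: np.ndarray, n_samples: int,
                   rng: np.random.Generator) -> tuple[float, float]:
    """i.i.d. random pairings of the gene copies (vectorized)."""
    k = tab.shape[0]
    a = (tab.sum(axis=0) + tab.sum(axis=1)).astype(np.int64)
    copies = np.repeat(np.arange(k), a)
    m = len(copies)
    t_obs = _hwe_log_stat(tab)
    cut = t_obs + _TIE_TOL * (1.0 + abs(t_obs))
    hits = 0
    batch = max(1, min(n_samples, max(1, 2_000_000 // max(m, 1))))
    done = 0
    lgam = gammaln(np.arange(m + 2) + 1.0)
    ln2 = math.log(2.0)
    while done < n_samples:
        b = min(batch, n_samples - done)
        keys = rng.random((b, m))
        perm = np.argsort(keys, axis=1)
        arr = copies[perm].reshape(b, m // 2, 2)
        i = arr.max(axis=2)
        j = arr.min(axis=2)
        het = (i != j).sum(axis=1)
        code = i * k + j
        stats = np.empty(b)
        for r in range(b):
            cnt = np.bincount(code[r], minlength=k * k)
            stats[r] = het[r] * ln2 - lgam[cnt].sum()
        hits += int((stats <= cut).sum())
        done += b
    p = (hits + 1) / (n_samples + 1)
    se = math.sqrt(p * (1 - p) / n_samples)
    return float(p), float(se)


def hwe_exact_test(
    genotype_counts: Mapping[tuple, int],
    *,
    method: str = "auto",
    max_tables: int = 1_000_000,
    n_steps: int = 1_000_000,
    burn_in: int = 100_000,
    n_samples: int = 100_000,
    seed: int | None = None,
    locus: str = "",
) -> TestResult:
    """Exact HWE test on one locus's diploid genotype counts.

    ``method='auto'`` fully enumerates the conditional state space when it
    holds at most ``max_tables`` tables and otherwise runs the
    transposition Markov chain.  ``'permutation'`` draws ``n_samples``
    i.i.d. random pairings instead.  Monomorphic input returns p = 1 with
    ``method='degenerate'``.
    """
    if not genotype_counts:
        raise ValueError("no genotypes")
    alleles, tab = _table_from_counts(genotype_counts)
    if len(alleles) < 2:
        return TestResult("hwe_exact", locus, 1.0, "degenerate")
    if method in ("auto", "enumeration"):
        try:
            p = _hwe_enumeration_p(tab, max_tables)
            return TestResult("hwe_exact", locus, p, "full_enumeration",
                              statistic=_hwe_log_stat(tab))
        except EnumerationTooLarge:
            if method == "enumeration":
                raise
    rng = np.random.default_rng(seed)
    if method == "permutation":
        p, se = _hwe_pairing_p(tab, n_samples, rng)
        return TestResult("hwe_exact", locus, p, "permutation",
                          n_steps=n_samples, seed=seed, standard_error=se,
                          statistic=_hwe_log_stat(tab))
    p, se = _hwe_chain_p(tab, n_steps, burn_in, rng)
    return TestResult("hwe_exact", locus, p, "markov_chain",
                      n_steps=n_steps, seed=seed, standard_error=se,
                      statistic=_hwe_log_stat(tab))


# ---------------------------------------------------------------------------
# Linkage disequilibrium, phase-known (male X haplotypes)
# ---------------------------------------------------------------------------

def _contingency(haplotypes: Sequence[tuple]) -> np.ndarray:
    xs = sorted({h[0] for h in haplotypes}, key=lambda v: allele_sort_key(str(v)))
    ys = sorted({h[1] for h in haplotypes}, key=lambda v: allele_sort_key(str(v)))
    xi = {a: i for i, a in enumerate(xs)}
    yi = {a: i for i, a in enumerate(ys)}
    tab = np.zeros((len(xs), len(ys)), dtype=np.int64)
    for a, b in haplotypes:
        tab[xi[a], yi[b]] += 1
    return tab


def _rc_log_stat(tab: np.ndarray) -> float:
    return -float(gammaln(tab + 1).sum())


def _enumerate_rc_tables(rows: np.ndarray, cols: np.ndarray, max_tables: int):
    r, c = len(rows), len(cols)
    if r * c > 100:
        raise EnumerationTooLarge  # recursion depth grows with cell count
    tab = np.zeros((r, c), dtype=np.int64)
    seen = 0
    nodes = 0
    node_budget = 40 * max_tables

    def fill(i: int, colrem: np.ndarray):
        nonlocal seen
        if i == r:
            seen += 1
            if seen > max_tables:
                raise EnumerationTooLarge
            yield tab
            return
        yield from cell(i, 0, int(rows[i]), colrem)

    def cell(i: int, j: int, left: int, colrem: np.ndarray):
        nonlocal nodes
        nodes += 1
        if nodes > node_budget:
            raise EnumerationTooLarge
        if j == c - 1:
            if left <= colrem[j]:
                tab[i, j] = left
                colrem[j] -= left
                yield from fill(i + 1, colrem)
                colrem[j] += left
            return
        hi = min(left, int(colrem[j]))
        lo = max(0, left - int(colrem[j + 1:].sum()))
        for v in range(hi, lo - 1, -1):
            tab[i, j] = v
            colrem[j] -= v
            yield from cell(i, j + 1, left - v, colrem)
            colrem[j] += v

    yield from fill(0, cols.astype(np.int64).copy())


def ld_exact_test_haploid(
    haplotypes: Sequence[tuple],
    *,
    max_tables: int = 200_000,
    n_permutations: int = 100_000,
    seed: int | None = None,
    loci: tuple[str, str] = ("", ""),
) -> TestResult:
    """Probability-ordering exact test of independence on phase-known
    two-locus haplotypes (an r×c contingency table with fixed margins).

    Generalizes the two-sided Fisher exact test; beyond the enumeration
    bound the null is sampled by permuting one locus's alleles.
    """
    tab = _contingency(haplotypes)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return TestResult("ld_exact_haploid", loci, 1.0, "degenerate")
    rows = tab.sum(axis=1)
    cols = tab.sum(axis=0)
    n = int(tab.sum())
    t_obs = _rc_log_stat(tab)
    cut = t_obs + _TIE_TOL * (1.0 + abs(t_obs))
    log_const = (gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
                 - gammaln(n + 1))
    try:
        p = 0.0
        total = 0.0
        for t in _enumerate_rc_tables(rows, cols, max_tables):
            s = _rc_log_stat(t)
            prob = math.exp(log_const + s)
            total += prob
            if s <= cut:
                p += prob
        if abs(total - 1.0) > 1e-8:
            raise RuntimeError(f"enumeration mass {total} != 1")
        return TestResult("ld_exact_haploid", loci, min(p, 1.0),
                          "full_enumeration", statistic=t_obs)
    except EnumerationTooLarge:
        pass
    rng = np.random.default_rng(seed)
    x = np.repeat(np.arange(tab.shape[0]), rows)
    y = np.repeat(np.arange(tab.shape[1]), cols)
    ncol = tab.shape[1]
    lgf = gammaln(np.arange(n + 2) + 1.0)
    hits = 0
    for _ in range(n_permutations):
        yp = rng.permutation(y)
        cnt = np.bincount(x * ncol + yp, minlength=tab.size)
        if -lgf[cnt].sum() <= cut:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    se = math.sqrt(p * (1 - p) / n_permutations)
    return TestResult("ld_exact_haploid", loci, float(p), "permutation",
                      n_steps=n_permutations, seed=seed, standard_error=se,
                      statistic=t_obs)


# ---------------------------------------------------------------------------
# Linkage disequilibrium, unphased diploid genotypes (female X / autosomal)
# ---------------------------------------------------------------------------

def _genotype_combos(genos: Sequence[tuple]):
    """Collapse individuals to unique two-locus genotype combos with counts.

    A combo is ((a1,a2),(b1,b2)) with each pair label-sorted.
    """
    combos: dict = {}
    for (g1, g2) in genos:
        a = tuple(sorted(g1, key=lambda v: allele_sort_key(str(v))))
        b = tuple(sorted(g2, key=lambda v: allele_sort_key(str(v))))
        combos[(a, b)] = combos.get((a, b), 0) + 1
    return combos


def _em_haplotypes(combos: Mapping, alleles1, alleles2,
                   tol: float = 1e-7, max_iter: int = 1000):
    """EM estimate of two-locus haplotype frequencies from unphased data.

    Phase resolutions are flattened into index arrays so each EM iteration
    is a handful of vectorized scatter/gather operations.  Returns
    (h flat [k1*k2], ll_alt, converged, ll_null) where ll_null evaluates the
    same data likelihood at linkage equilibrium (product frequencies).
    """
    i1 = {a: i for i, a in enumerate(alleles1)}
    i2 = {a: i for i, a in enumerate(alleles2)}
    k1, k2 = len(alleles1), len(alleles2)
    n = sum(combos.values())

    # one row per phase resolution: combo id, flat haplotype ids, coeff
    combo_id: list[int] = []
    hapA: list[int] = []
    hapB: list[int] = []
    coeff: list[float] = []
    counts: list[float] = []
    p1 = np.zeros(k1)
    p2 = np.zeros(k2)
    for ci, (((a1, a2), (b1, b2)), c) in enumerate(combos.items()):
        counts.append(float(c))
        p1[i1[a1]] += c
        p1[i1[a2]] += c
        p2[i2[b1]] += c
        p2[i2[b2]] += c
        seen = set()
        for hA, hB in (((a1, b1), (a2, b2)), ((a1, b2), (a2, b1))):
            key = tuple(sorted((hA, hB)))
            if key in seen:
                continue
            seen.add(key)
            hA2, hB2 = key
            combo_id.append(ci)
            hapA.append(i1[hA2[0]] * k2 + i2[hA2[1]])
            hapB.append(i1[hB2[0]] * k2 + i2[hB2[1]])
            coeff.append(1.0 if hA2 == hB2 else 2.0)
    combo_id = np.array(combo_id)
    hapA = np.array(hapA)
    hapB = np.array(hapB)
    coeff = np.array(coeff)
    counts = np.array(counts)
    n_combo = len(counts)

    p1 /= p1.sum()
    p2 /= p2.sum()
    h0 = np.outer(p1, p2).ravel()

    def loglik(h):
        pr = np.bincount(combo_id, weights=coeff * h[hapA] * h[hapB],
                         minlength=n_combo)
        return float(counts @ np.log(np.maximum(pr, 1e-300)))

    def run_em(h):
        converged = False
        for _ in range(max_iter):
            w = coeff * h[hapA] * h[hapB]
            tot = np.bincount(combo_id, weights=w, minlength=n_combo)
            tot = np.maximum(tot, 1e-300)
            share = counts[combo_id] * w / tot[combo_id]
            new = (np.bincount(hapA, weights=share, minlength=k1 * k2)
                   + np.bincount(hapB, weights=share, minlength=k1 * k2))
            new /= 2.0 * n
            delta = float(np.abs(new - h).max())
            h = new
            if delta < tol:
                converged = True
                break
        return h, loglik(h), converged

    # the product start is a stationary point for perfectly symmetric data
    # (e.g. all double heterozygotes); deterministic jittered restarts break
    # the saddle so EM can climb to the association maximum
    jitter = np.random.default_rng(12345)
    starts = [h0]
    for _ in range(2):
        hj = h0 * (1.0 + 0.05 * jitter.random(h0.shape))
        starts.append(hj / hj.sum())
    best = None
    for h_start in starts:
        h, ll, conv = run_em(h_start.copy())
        if best is None or ll > best[1] + 1e-12:
            best = (h, ll, conv)
    h, ll, converged = best
    return h, ll, converged, loglik(h0)


def _lrt_stat(genos: Sequence[tuple]) -> tuple[float, bool]:
    combos = _genotype_combos(genos)
    alleles1 = sorted({a for (g1, _g2) in combos for a in g1},
                      key=lambda v: allele_sort_key(str(v)))
    alleles2 = sorted({b for (_g1, g2) in combos for b in g2},
                      key=lambda v: allele_sort_key(str(v)))
    _h, ll_alt, conv, ll_null = _em_haplotypes(combos, alleles1, alleles2)
    return max(0.0, 2.0 * (ll_alt - ll_null)), conv


def ld_test_genotypic(
    genotype_pairs: Sequence[tuple],
    *,
    n_permutations: int = 10_000,
    seed: int | None = None,
    loci: tuple[str, str] = ("", ""),
) -> TestResult:
    """Likelihood-ratio LD test for unphased diploid two-locus genotypes.

    Haplotype frequencies under association are fitted by EM; the null model
    is linkage equilibrium (product of allele frequencies).  Significance by
    permuting one locus's genotypes between individuals, which preserves
    both single-locus genotype distributions while breaking association.
    """
    genos = [g for g in genotype_pairs
             if None not in g[0] and None not in g[1]]
    if not genos:
        raise ValueError("no complete two-locus genotypes")
    a1 = {a for g, _ in genos for a in g}
    a2 = {b for _, g in genos for b in g}
    if len(a1) < 2 or len(a2) < 2:
        return TestResult("ld_genotypic_em", loci, 1.0, "degenerate")
    t_obs, conv = _lrt_stat(genos)
    rng = np.random.default_rng(seed)
    g1s = [g for g, _ in genos]
    g2s = [g for _, g in genos]
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(genos))
        t, _ = _lrt_stat([(g1s[i], g2s[j]) for i, j in enumerate(perm)])
        if t >= t_obs - _TIE_TOL:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    se = math.sqrt(p * (1 - p) / n_permutations)
    return TestResult("ld_genotypic_em", loci, float(p),
                      "likelihood_ratio_em", n_steps=n_permutations,
                      seed=seed, standard_error=se, statistic=t_obs,
                      converged=conv)


# ---------------------------------------------------------------------------
# Multiple testing / bookkeeping
# ---------------------------------------------------------------------------

def bonferroni(p_values: Sequence[float], alpha: float = 0.05
               ) -> tuple[float, list[bool]]:
    """Family-wise threshold alpha/m and per-test decisions (p < threshold).

    ``m`` is always the actual number of tests supplied.
    """
    m = len(p_values)
    if m < 1:
        raise ValueError("need at least one test")
    thr = alpha / m
    return thr, [p < thr for p in p_values]


def pair_enumeration(loci: Sequence[str]) -> list[tuple[str, str]]:
    """All C(k,2) unordered locus pairs in deterministic input order."""
    if len(loci) < 2:
        raise ValueError("need at least two loci")
    return list(itertools.combinations(loci, 2))
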