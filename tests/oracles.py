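"""Independent brute-force oracles used only by the test suite.

Every function here enumerates genotype or pedigree configurations with
plain nested loops over HWE probabilities — deliberately naive and written
without reference to the package's closed forms or vectorized enumerations.
"""

import numpy as np


def genotypes(p):
    """All unordered diploid genotypes (i <= j) with HWE probabilities."""
    k = len(p)
    for i in range(k):
        for j in range(i, k):
            prob = p[i] ** 2 if i == j else 2 * p[i] * p[j]
            yield (i, j), prob


def pic_double_sum(p):
    """1 - Σp² - ΣΣ_{i≠j} p_i² p_j²."""
    k = len(p)
    total = 1.0 - sum(x * x for x in p)
    for i in range(k):
        for j in range(k):
            if i != j:
                total -= p[i] ** 2 * p[j] ** 2
    return total


def match_probability_hwe(p):
    return sum(prob**2 for _, prob in genotypes(p))


def pd_female_enum(p):
    return 1.0 - match_probability_hwe(p)


def pe_duo_enum(p):
    """Autosomal duo: random man shares no allele with a random child."""
    total = 0.0
    for (ci, cj), cprob in genotypes(p):
        child = {ci, cj}
        for (mi, mj), mprob in genotypes(p):
            if mi not in child and mj not in child:
                total += cprob * mprob
    return total


def pe_trio_enum(p):
    """Autosomal trio: paternal allele set deduced from mother+child."""
    k = len(p)
    total = 0.0
    for mi in range(k):          # maternal transmitted
        for mj in range(k):      # maternal other (ordered mother genotype)
            for f in range(k):   # true paternal allele
                w = p[mi] * p[mj] * p[f]
                if f != mi and mj == f:
                    S = {f, mi}  # mother carries both child alleles
                else:
                    S = {f}
                for (xi, xj), xprob in genotypes(p):
                    if xi not in S and xj not in S:
                        total += w * xprob
    return total


def mec_duo_enum(p):
    """X father-daughter duo: man's single allele outside daughter's pair."""
    k = len(p)
    total = 0.0
    for (ci, cj), cprob in genotypes(p):
        child = {ci, cj}
        for a in range(k):
            if a not in child:
                total += cprob * p[a]
    return total


def mec_trio_enum(p):
    """X trio: hemizygous man's allele outside the compatible paternal set."""
    k = len(p)
    total = 0.0
    for mi in range(k):
        for mj in range(k):
            for f in range(k):
                w = p[mi] * p[mj] * p[f]
                if f != mi and mj == f:
                    S = {f, mi}
                else:
                    S = {f}
                for a in range(k):
                    if a not in S:
                        total += w * p[a]
    return total


def mec_kruger_enum(p):
    """X deficiency case: diploid grandmother carries no compatible allele."""
    k = len(p)
    total = 0.0
    for mi in range(k):
        for mj in range(k):
            for f in range(k):
                w = p[mi] * p[mj] * p[f]
                if f != mi and mj == f:
                    S = {f, mi}
                else:
                    S = {f}
                for (gi, gj), gprob in genotypes(p):
                    if gi not in S and gj not in S:
                        total += w * gprob
    return total


def random_additive_matrix(rng, n_taxa):
    """Random additive (tree-metric) distance matrix with its generating
    topology implicit; built by agglomerative joining with positive branch
    lengths, accumulating leaf-to-leaf path lengths directly."""
    labels = [f"T{i}" for i in range(n_taxa)]
    clusters = [[i] for i in range(n_taxa)]
    depth = {i: 0.0 for i in range(n_taxa)}  # leaf -> distance to its cluster root
    dist = np.zeros((n_taxa, n_taxa))
    while len(clusters) > 1:
        a, b = sorted(rng.choice(len(clusters), size=2, replace=False))
        ba = rng.uniform(0.1, 1.0)
        bb = rng.uniform(0.1, 1.0)
        for leaf in clusters[a]:
            depth[leaf] += ba
        for leaf in clusters[b]:
            depth[leaf] += bb
        for la in clusters[a]:
            for lb in clusters[b]:
                d = depth[la] + depth[lb]
                dist[la, lb] = dist[lb, la] = d
        merged = clusters[a] + clusters[b]
        clusters = [c for t, c in enumerate(clusters) if t not in (a, b)]
        clusters.append(merged)
    return labels, dist
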