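"""Independent reference implementations used only as test oracles.

Each function is written as plainly as possible (explicit loops, library-free
combinatorics) and stays independent of the package code paths it checks.
"""

import itertools
import math

import numpy as np


def reference_network_edges(stack, corr_cutoff=0.6, support_fraction=0.25):
    """Triple-loop edge rule: qualify on |r|, check support and sign agreement."""
    genes = stack.gene_ids
    n = stack.n_individuals
    edges = set()
    for i, j in itertools.combinations(range(len(genes)), 2):
        rs = []
        for ind in stack.individual_ids:
            r = stack.matrices[ind][i, j]
            if not math.isnan(r) and abs(r) >= corr_cutoff:
                rs.append(r)
        if not rs or len(rs) / n < support_fraction:
            continue
        if all(r > 0 for r in rs) or all(r < 0 for r in rs):
            edges.add(tuple(sorted((genes[i], genes[j]))))
    return edges


def reference_frobenius(a: np.ndarray, b: np.ndarray) -> float:
    """Double-loop full-matrix Frobenius distance, NaN pairs omitted."""
    total = 0.0
    n = a.shape[0]
    for i in range(n):
        for j in range(n):
            x, y = a[i, j], b[i, j]
            if math.isnan(x) or math.isnan(y):
                continue
            total += abs(x - y) ** 2
    return math.sqrt(total)


def reference_bh(p_values):
    """Plain Benjamini-Hochberg step-up, stable-sorted, capped at 1."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [1.0 * m * p[order[i]] / (i + 1) for i in range(m)]
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = [0.0] * m
    for rank, idx in enumerate(order):
        q[idx] = min(q_sorted[rank], 1.0)
    return q


def reference_hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by explicit summation of the hypergeometric mass function."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


def reference_paired_t(d):
    """One-sample t on a vector of paired differences, from the formula."""
    d = list(map(float, d))
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    return mean / math.sqrt(var / n)


def all_bipartitions(nodes):
    """Every split of `nodes` into two non-empty parts (no mirror duplicates)."""
    nodes = list(nodes)
    first = nodes[0]
    rest = nodes[1:]
    for r in range(len(rest) + 1):
        for combo in itertools.combinations(rest, r):
            part_a = {first, *combo}
            part_b = set(nodes) - part_a
            if part_b:
                yield part_a, part_b
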