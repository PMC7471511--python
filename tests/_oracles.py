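"""Independent reference implementations used only to check the package.

Everything here is written from first principles (exact combinatorics,
brute-force scans, naive O(n^2) loops) and deliberately shares no code with
the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def hypergeom_pmf(N: int, K: int, n: int, k: int) -> float:
    """Exact hypergeometric pmf by integer combinatorics."""
    if k < max(0, n + K - N) or k > min(n, K):
        return 0.0
    return math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)


def hypergeom_oracle(N: int, K: int, n: int, k: int):
    """(expected, sd, z, p) by direct summation of the pmf."""
    expected = n * K / N
    var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1)
    sd = math.sqrt(var)
    z = (k - expected) / sd if sd > 0 else 0.0
    if sd == 0:
        return expected, sd, 0.0, 1.0
    if k >= expected:
        p = sum(hypergeom_pmf(N, K, n, j) for j in range(k, min(n, K) + 1))
    else:
        p = sum(hypergeom_pmf(N, K, n, j) for j in range(0, k + 1))
    return expected, sd, z, min(p, 1.0)


def brute_force_clusters(centres_by_chrom: dict, threshold: int):
    """Index-anchored clustering by repeated scans over unassigned peaks.

    ``centres_by_chrom``: chrom -> list of (centre, tag).  Returns a list of
    frozensets of tags, one per cluster.
    """
    clusters = []
    for chrom in sorted(centres_by_chrom):
        peaks = sorted(centres_by_chrom[chrom])
        unassigned = list(peaks)
        while unassigned:
            index = unassigned[0]
            members = [p for p in unassigned if p[0] - index[0] < threshold]
            clusters.append(frozenset(tag for _, tag in members))
            unassigned = [p for p in unassigned if p not in members]
    return clusters


def spearman_pair(x, y) -> float:
    """Spearman correlation of two vectors via average ranks."""
    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def naive_topk_edges(values, gene_ids, k: int = 3):
    """All-pairs Spearman, per-gene top-k by (rho desc, partner id asc),
    symmetrised into a set of undirected edges."""
    n = len(gene_ids)
    rho = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rho[i, j] = rho[j, i] = spearman_pair(values[i], values[j])
    edges = set()
    for i in range(n):
        partners = sorted(
            (j for j in range(n) if j != i),
            key=lambda j: (-rho[i, j], gene_ids[j]),
        )[:k]
        for j in partners:
            edges.add(tuple(sorted((gene_ids[i], gene_ids[j]))))
    return edges, rho


def newman_modularity(edges, weights, membership: dict) -> float:
    """Weighted Newman modularity from the definition:
    Q = sum_c (w_in_c / W - (deg_c / 2W)^2) with W the total edge weight."""
    W = sum(weights)
    deg: dict = {}
    w_in: dict = {}
    for (a, b), w in zip(edges, weights):
        deg[a] = deg.get(a, 0.0) + w
        deg[b] = deg.get(b, 0.0) + w
        if membership[a] == membership[b]:
            c = membership[a]
            w_in[c] = w_in.get(c, 0.0) + w
    q = 0.0
    communities = set(membership.values())
    for c in communities:
        dc = sum(d for node, d in deg.items() if membership[node] == c)
        q += w_in.get(c, 0.0) / W - (dc / (2 * W)) ** 2
    return q


def window_mean_oracle(intervals, start: int, end: int) -> float:
    """Length-weighted mean of stepwise intervals over [start, end);
    uncovered bases contribute 0."""
    total = 0.0
    for s, e, v in intervals:
        lo, hi = max(s, start), min(e, end)
        if hi > lo:
            total += v * (hi - lo)
    return total / (end - start)
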