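"""Independent brute-force oracles used by the unit and acceptance tests.

Each function re-derives an expected result by the most naive correct
algorithm available (all-pairs scans, union-find, explicit enumeration,
closed-form formulas) so the tested implementations are checked against
logic that shares none of their code paths.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def union_find_merge(intervals, min_gap=0):
    """O(n^2) union-find merge of (chrom, start, end) tuples."""
    items = list(intervals)
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            ci, si, ei = items[i]
            cj, sj, ej = items[j]
            if ci == cj and si < ej + min_gap and sj < ei + min_gap:
                union(i, j)
    groups = {}
    for i in range(len(items)):
        groups.setdefault(find(i), []).append(items[i])
    merged = []
    for members in groups.values():
        chrom = members[0][0]
        merged.append((chrom, min(s for _, s, _ in members), max(e for _, _, e in members)))
    return sorted(merged)


def vote_rule(matrix, min_tools=2, min_pools=2):
    """Explicit evaluation of the tools-x-pools vote on a boolean matrix
    (rows = tools, columns = pools)."""
    m = np.asarray(matrix, dtype=bool)
    pools_ok = sum(int(m[:, p].sum() >= min_tools) for p in range(m.shape[1]))
    return pools_ok >= min_pools


def all_pairs_tss_hits(anchors_by_chrom, genes, window):
    """Exhaustive |anchor - tss| <= window scan; genes are
    (gene_id, chrom, tss) tuples."""
    hits = set()
    for gene_id, chrom, tss in genes:
        for a in anchors_by_chrom.get(chrom, []):
            if abs(a - tss) <= window:
                hits.add(gene_id)
                break
    return hits


def all_pairs_span_hits(peaks, spans):
    """Exhaustive interval-overlap scan; peaks are (chrom, start, end),
    spans are (gene_id, chrom, start, end)."""
    hits = set()
    for gene_id, chrom, s, e in spans:
        for pc, ps, pe in peaks:
            if pc == chrom and ps < e and s < pe:
                hits.add(gene_id)
                break
    return hits


def pooled_t_test(x, y):
    """Closed-form pooled-variance (Student's) two-sided t-test."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (
        nx + ny - 2
    )
    t = (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * stats.t.sf(abs(t), nx + ny - 2)
    return float(t), float(p)


def naive_upgma_heights(D):
    """Naive O(n^3) average-linkage agglomeration; returns the sequence of
    merge heights (ascending). D is a square distance matrix."""
    D = np.asarray(D, float)
    clusters = {i: [i] for i in range(D.shape[0])}
    heights = []
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for ai, a in enumerate(keys):
            for b in keys[ai + 1 :]:
                d = float(
                    np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters.pop(b)
    return heights
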