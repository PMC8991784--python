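"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: modularity maxima come
from exhaustive enumeration of set partitions, transitivity from an O(V^3)
triple scan, Spearman from explicit average ranks followed by Pearson on
the ranks, and shared-patient counts from pairwise panel intersections.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def set_partitions(items):
    """Yield every partition of ``items`` as a list of lists."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] + [first]] + smaller[i + 1:]
        yield [[first]] + smaller


def modularity_of(graph, blocks, weight="weight"):
    """Direct evaluation of weighted Newman-Girvan Q for a block list."""
    m = graph.size(weight=weight)
    label = {v: i for i, block in enumerate(blocks) for v in block}
    intra = sum(d.get(weight, 1.0) for a, b, d in graph.edges(data=True)
                if label[a] == label[b])
    deg = dict(graph.degree(weight=weight))
    tot = [0.0] * len(blocks)
    for v, k in deg.items():
        tot[label[v]] += k
    return intra / m - sum(t * t for t in tot) / (4.0 * m * m)


def best_partition_exhaustive(graph, weight="weight"):
    """Global modularity optimum by enumerating all set partitions."""
    best_q, best_blocks = -math.inf, None
    for blocks in set_partitions(list(graph.nodes)):
        q = modularity_of(graph, blocks, weight)
        if q > best_q:
            best_q, best_blocks = q, blocks
    return best_q, best_blocks


def brute_transitivity(graph):
    """3 * triangles / connected triples via an O(V^3) scan; NaN if no
    triples (integer counts before the final division)."""
    nodes = list(graph.nodes)
    triangles = triples = 0
    for a, b, c in itertools.combinations(nodes, 3):
        ab, bc, ac = graph.has_edge(a, b), graph.has_edge(b, c), graph.has_edge(a, c)
        n_edges = ab + bc + ac
        if n_edges == 3:
            triangles += 1
            triples += 3
        elif n_edges == 2:
            triples += 1
    if triples == 0:
        return float("nan")
    return 3.0 * triangles / triples


def average_ranks(x):
    """Average ranks (1-based) with ties sharing the mean rank."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Spearman rho as Pearson on average ranks; t-approximation p-value."""
    from scipy.stats import t as tdist

    rx, ry = average_ranks(x), average_ranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(rx)
    if abs(rho) >= 1.0:
        return rho, 0.0
    tstat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * tdist.sf(abs(tstat), df=n - 2)
    return rho, p


def brute_shared_counts(consultations):
    """Shared distinct patients per physician pair via set intersections."""
    panels: dict[str, set[str]] = {}
    for _, row in consultations.iterrows():
        panels.setdefault(row["physician_id"], set()).add(row["patient_id"])
    out = {}
    for a, b in itertools.combinations(sorted(panels), 2):
        n = len(panels[a] & panels[b])
        if n:
            out[(a, b)] = n
    return out
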