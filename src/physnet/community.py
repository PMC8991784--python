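"""Modularity-based community detection with a network-size band.

The sharing graph is partitioned by greedy multilevel (Louvain-style)
modularity maximisation, applied *iteratively*: any community larger than
``max_network_size`` is re-partitioned on its own induced subgraph (intra-
community edges at original weights) until all communities fit the
[``min_network_size``, ``max_network_size``] band or cannot be split
further.  Communities that end below the minimum size are discarded;
communities the algorithm cannot split are retained even if oversized and
flagged.

The multilevel implementation here is fully deterministic under a fixed
seed: the vertex visiting order is a seeded shuffle renewed each local-
moving pass, and among equal-gain target communities the lowest community
label wins.  Modularity is the standard weighted Newman-Girvan quality

    Q = (1/2m) * sum_ij [w_ij - k_i k_j / (2m)] * delta(c_i, c_j)

with weighted degrees k and total edge weight m, at resolution 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import ValidationError
from .io import write_table
from .sharing import SharingGraph

log = logging.getLogger(__name__)

_EPS = 1e-12


def _as_nx(graph: SharingGraph | nx.Graph) -> nx.Graph:
    return graph.graph if isinstance(graph, SharingGraph) else graph


def modularity(graph: SharingGraph | nx.Graph,
               partition: Mapping[Hashable, Hashable],
               weight: str = "weight") -> float:
    """Weighted Newman-Girvan modularity of a full vertex partition."""
    g = _as_nx(graph)
    missing = set(g.nodes) - set(partition)
    if missing:
        raise ValidationError(
            f"partition does not cover vertices: {sorted(map(str, missing))[:5]}")
    m = g.size(weight=weight)
    if m <= 0:
        raise ValidationError(
            "modularity undefined: graph has zero total edge weight")
    degree = dict(g.degree(weight=weight))
    intra = 0.0
    for a, b, d in g.edges(data=True):
        if partition[a] == partition[b]:
            intra += d.get(weight, 1.0)
    tot: dict[Hashable, float] = {}
    for v, k in degree.items():
        tot[partition[v]] = tot.get(partition[v], 0.0) + k
    return intra / m - sum(t * t for t in tot.values()) / (4.0 * m * m)


class _Level:
    """One aggregation level: adjacency dicts + self-loop (internal) weight."""

    __slots__ = ("adj", "selfw", "k", "m")

    def __init__(self, adj: list[dict[int, float]], selfw: list[float]):
        self.adj = adj
        self.selfw = selfw
        self.k = [sum(nbrs.values()) + 2.0 * s
                  for nbrs, s in zip(adj, selfw)]
        self.m = sum(self.k) / 2.0


def _local_moving(level: _Level, comm: list[int],
                  rng: np.random.Generator) -> bool:
    """Repeated passes of greedy single-vertex moves; returns whether any
    vertex moved."""
    n = len(level.adj)
    m = level.m
    tot = [0.0] * n
    for v in range(n):
        tot[comm[v]] += level.k[v]
    moved_any = False
    order = np.arange(n)
    while True:
        rng.shuffle(order)
        moved_this_pass = False
        for v in order:
            v = int(v)
            old = comm[v]
            kv = level.k[v]
            tot[old] -= kv
            # weight from v to each neighboring community
            links: dict[int, float] = {}
            for u, w in level.adj[v].items():
                links[comm[u]] = links.get(comm[u], 0.0) + w
            # score(C) ∝ gain of inserting the isolated v into C
            best_label = old
            best_score = links.get(old, 0.0) - tot[old] * kv / (2.0 * m)
            for c in sorted(links):
                if c == old:
                    continue
                score = links[c] - tot[c] * kv / (2.0 * m)
                if score > best_score + _EPS or (
                        abs(score - best_score) <= _EPS and c < best_label):
                    best_label, best_score = c, score
            comm[v] = best_label
            tot[best_label] += kv
            if best_label != old:
                moved_this_pass = True
                moved_any = True
        if not moved_this_pass:
            break
    return moved_any


def _aggregate(level: _Level, comm: list[int]) -> tuple[_Level, list[int]]:
    """Collapse communities into super-vertices; returns the new level and
    the mapping old-vertex -> new-vertex."""
    labels = sorted(set(comm))
    relabel = {c: i for i, c in enumerate(labels)}
    mapping = [relabel[c] for c in comm]
    k = len(labels)
    adj: list[dict[int, float]] = [dict() for _ in range(k)]
    selfw = [0.0] * k
    for v, nbrs in enumerate(level.adj):
        cv = mapping[v]
        selfw[cv] += level.selfw[v]
        for u, w in nbrs.items():
            if u <= v:
                continue
            cu = mapping[u]
            if cu == cv:
                selfw[cv] += w
            else:
                adj[cv][cu] = adj[cv].get(cu, 0.0) + w
                adj[cu][cv] = adj[cu].get(cv, 0.0) + w
    return _Level(adj, selfw), mapping


def multilevel_partition(graph: SharingGraph | nx.Graph,
                         seed: int = 0,
                         weight: str = "weight") -> dict[Hashable, int]:
    """One full multilevel run; labels are 0..k-1 ordered by each
    community's smallest vertex id."""
    g = _as_nx(graph)
    nodes = sorted(g.nodes, key=str)
    if not nodes:
        return {}
    index = {v: i for i, v in enumerate(nodes)}
    if g.number_of_edges() == 0:
        log.warning("graph has no edges; every vertex is its own community "
                    "and modularity is undefined")
        return {v: i for i, v in enumerate(nodes)}

    adj: list[dict[int, float]] = [dict() for _ in nodes]
    for a, b, d in g.edges(data=True):
        if a == b:
            continue
        w = float(d.get(weight, 1.0))
        ia, ib = index[a], index[b]
        adj[ia][ib] = adj[ia].get(ib, 0.0) + w
        adj[ib][ia] = adj[ib].get(ia, 0.0) + w
    level = _Level(adj, [0.0] * len(nodes))

    rng = np.random.default_rng(seed)
    membership = list(range(len(nodes)))          # original vertex -> current super-vertex
    while True:
        comm = list(range(len(level.adj)))
        moved = _local_moving(level, comm, rng)
        new_level, mapping = _aggregate(level, comm)
        membership = [mapping[m] for m in membership]
        if not moved or len(new_level.adj) == len(level.adj):
            break
        level = new_level

    # stable labels: communities ordered by their smallest member
    first_seen: dict[int, int] = {}
    for i, v in enumerate(nodes):
        first_seen.setdefault(membership[i], len(first_seen))
    return {v: first_seen[membership[i]] for i, v in enumerate(nodes)}


@dataclass
class NetworkPartition:
    """Final physician -> network assignment under the size band."""

    assignment: dict[str, str]
    networks: dict[str, frozenset[str]]
    discarded: set[str]
    oversized: set[str] = field(default_factory=set)   # flagged terminal networks
    trace: list[dict] = field(default_factory=list)

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trace)


def iterative_split(graph: SharingGraph | nx.Graph,
                    config: PipelineConfig,
                    seed: int | None = None) -> NetworkPartition:
    """Recursive multilevel splitting until the size band is met."""
    g = _as_nx(graph)
    if seed is None:
        seed = config.seed
    lo, hi = config.min_network_size, config.max_network_size

    final: list[tuple[frozenset, bool]] = []     # (members, oversized-terminal)
    trace: list[dict] = []
    queue: list[tuple[frozenset, str]] = [(frozenset(g.nodes), "root")]
    task = 0
    while queue:
        members, sub_id = queue.pop(0)
        sub = g.subgraph(members)
        part = multilevel_partition(sub, seed=(seed + task) % 2**31)
        task += 1
        comms: dict[int, set] = {}
        for v, c in part.items():
            comms.setdefault(c, set()).add(v)
        sizes = sorted((len(c) for c in comms.values()), reverse=True)
        q = modularity(sub, part) if sub.number_of_edges() else float("nan")
        terminal = len(comms) == 1
        trace.append({
            "subgraph_id": sub_id, "n_vertices": len(members),
            "n_edges": sub.number_of_edges(), "q": q,
            "n_communities": len(comms), "sizes": sizes,
            "terminal": terminal,
        })
        if terminal:
            final.append((frozenset(members), len(members) > hi))
            if len(members) > hi:
                log.warning("community of %d physicians could not be split "
                            "below %d; retained and flagged", len(members), hi)
            continue
        for label in sorted(comms):
            c = comms[label]
            if len(c) > hi:
                queue.append((frozenset(c), f"{sub_id}/{label}"))
            else:
                final.append((frozenset(c), False))

    retained = [(m, flag) for m, flag in final if len(m) >= lo]
    discarded = set().union(*(m for m, _ in final if len(m) < lo)) \
        if any(len(m) < lo for m, _ in final) else set()

    retained.sort(key=lambda t: (-len(t[0]), min(t[0])))
    width = max(3, len(str(len(retained))))
    networks: dict[str, frozenset[str]] = {}
    oversized: set[str] = set()
    assignment: dict[str, str] = {}
    for i, (m, flag) in enumerate(retained, start=1):
        nid = f"N{i:0{width}d}"
        networks[nid] = m
        if flag:
            oversized.add(nid)
        for v in m:
            assignment[v] = nid

    log.info("iterative split: %d networks retained (%d flagged oversized), "
             "%d physicians discarded in undersized communities",
             len(networks), len(oversized), len(discarded))
    return NetworkPartition(assignment=assignment, networks=networks,
                            discarded=discarded, oversized=oversized,
                            trace=trace)


def write_partition(partition: NetworkPartition, path: str | Path) -> None:
    path = Path(path)
    rows = sorted(partition.assignment.items())
    write_table(pd.DataFrame(rows, columns=["physician_id", "network_id"]),
                path / "networks.csv")
    write_table(pd.DataFrame({"physician_id": sorted(partition.discarded)}),
                path / "discarded.csv")
    tf = partition.trace_frame()
    if len(tf):
        tf = tf.assign(sizes=tf["sizes"].map(
            lambda s: "|".join(map(str, s))))
    write_table(tf, path / "trace.csv")
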