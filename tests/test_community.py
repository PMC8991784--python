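"""Modularity, deterministic multilevel detection, size-constrained splitting."""

import itertools

import networkx as nx
import numpy as np
import pytest

from physnet import (PipelineConfig, ValidationError, iterative_split,
                     modularity, multilevel_partition, partition_ari)

from oracles import best_partition_exhaustive, modularity_of


def _clique(g, ids, w=1.0):
    for a, b in itertools.combinations(ids, 2):
        g.add_edge(a, b, weight=w)


def _two_cliques(n=10, bridge=True):
    g = nx.Graph()
    _clique(g, [f"a{i}" for i in range(n)])
    _clique(g, [f"b{i}" for i in range(n)])
    if bridge:
        g.add_edge("a0", "b0", weight=1.0)
    return g


def test_modularity_two_disjoint_triangles_is_half():
    g = nx.Graph()
    _clique(g, "abc")
    _clique(g, "xyz")
    part = {v: ("t1" if v in "abc" else "t2") for v in g}
    assert modularity(g, part) == pytest.approx(0.5)


def test_modularity_single_community_is_zero():
    g = _two_cliques()
    assert modularity(g, {v: 0 for v in g}) == pytest.approx(0.0)


def test_modularity_singletons_is_negative_sum_of_squares():
    g = nx.Graph()
    g.add_edge("a", "b", weight=2.0)
    g.add_edge("b", "c", weight=1.0)
    m = 3.0
    expected = -sum((k / (2 * m)) ** 2
                    for _, k in g.degree(weight="weight"))
    assert modularity(g, {v: v for v in g}) == pytest.approx(expected)


def test_modularity_requires_full_cover_and_edges():
    g = _two_cliques()
    with pytest.raises(ValidationError):
        modularity(g, {"a0": 0})
    empty = nx.Graph()
    empty.add_nodes_from("ab")
    with pytest.raises(ValidationError):
        modularity(empty, {"a": 0, "b": 0})


def test_modularity_agrees_with_networkx(rng):
    """Cross-check the Q formula against the independent networkx routine."""
    from networkx.algorithms.community import modularity as nx_modularity

    for _ in range(10):
        g = nx.gnp_random_graph(12, 0.4, seed=int(rng.integers(2**31)))
        for a, b in g.edges:
            g[a][b]["weight"] = float(rng.integers(1, 6))
        if g.number_of_edges() == 0:
            continue
        labels = {v: int(rng.integers(3)) for v in g}
        blocks = [{v for v in g if labels[v] == c} for c in range(3)]
        blocks = [b for b in blocks if b]
        assert modularity(g, labels) == pytest.approx(
            nx_modularity(g, blocks, weight="weight"), abs=1e-12)


def test_multilevel_recovers_two_cliques_exactly():
    g = _two_cliques()
    part = multilevel_partition(g, seed=0)
    labels = {frozenset(v for v in g if part[v] == c) for c in set(part.values())}
    assert labels == {frozenset(f"a{i}" for i in range(10)),
                      frozenset(f"b{i}" for i in range(10))}
    q_best, _ = best_partition_exhaustive(_small_two_cliques())
    # and on a size where exhaustive search is feasible, the clique split
    # is the global optimum reached exactly
    small = _small_two_cliques()
    sp = multilevel_partition(small, seed=0)
    assert modularity(small, sp) == pytest.approx(q_best, abs=1e-9)


def _small_two_cliques():
    g = nx.Graph()
    _clique(g, ["a0", "a1", "a2", "a3"])
    _clique(g, ["b0", "b1", "b2", "b3"])
    g.add_edge("a0", "b0", weight=1.0)
    return g


def test_edgeless_graph_yields_singletons():
    g = nx.Graph()
    g.add_nodes_from(["v1", "v2", "v3"])
    part = multilevel_partition(g, seed=0)
    assert sorted(part.values()) == [0, 1, 2]


def test_multilevel_never_beats_exhaustive_small(rng):
    """Greedy Q <= global optimum on random graphs small enough to
    enumerate every partition."""
    for _ in range(8):
        n = int(rng.integers(4, 8))
        g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
        if g.number_of_edges() == 0:
            continue
        for a, b in g.edges:
            g[a][b]["weight"] = float(rng.integers(1, 5))
        q_best, _ = best_partition_exhaustive(g)
        q_found = modularity(g, multilevel_partition(g, seed=1))
        assert q_found <= q_best + 1e-9


def test_planted_partition_recovery(rng):
    """Four strongly intra-connected blocks are recovered (ARI >= 0.9)."""
    g = nx.Graph()
    truth = {}
    for c in range(4):
        ids = [f"c{c}v{i}" for i in range(25)]
        for v in ids:
            truth[v] = c
        for a, b in itertools.combinations(ids, 2):
            if rng.random() < 0.6:
                g.add_edge(a, b, weight=int(rng.integers(20, 60)))
    nodes = sorted(g.nodes)
    for _ in range(150):
        a, b = rng.choice(len(nodes), 2, replace=False)
        a, b = nodes[a], nodes[b]
        if truth[a] != truth[b] and not g.has_edge(a, b):
            g.add_edge(a, b, weight=int(rng.integers(1, 5)))
    part = multilevel_partition(g, seed=3)
    assert partition_ari(part, truth) >= 0.9


def test_determinism_same_seed_same_partition():
    g = _two_cliques(n=12)
    for a, b in list(g.edges)[::3]:
        g[a][b]["weight"] = 3.0
    assert multilevel_partition(g, seed=5) == multilevel_partition(g, seed=5)
    res1 = iterative_split(g, PipelineConfig(min_network_size=5,
                                             max_network_size=12), seed=9)
    res2 = iterative_split(g, PipelineConfig(min_network_size=5,
                                             max_network_size=12), seed=9)
    assert res1.assignment == res2.assignment
    assert res1.networks == res2.networks


def _two_level_fixture():
    """A graph whose first-level communities are {200, 60, 15} and whose
    200-community splits into {90, 110} on its own subgraph (the coupling
    between the two blocks sits inside the resolution-limit window)."""
    rng = np.random.default_rng(42)
    g = nx.Graph()
    a1 = [f"a{i:03d}" for i in range(90)]
    a2 = [f"b{i:03d}" for i in range(110)]
    b = [f"c{i:03d}" for i in range(60)]
    c = [f"d{i:03d}" for i in range(15)]
    for ids, w in ((a1, 1.0), (a2, 1.0), (b, 50.0), (c, 1.0)):
        _clique(g, ids, w)
    for x in a1:
        for y in a2:
            if rng.random() < 0.3:
                g.add_edge(x, y, weight=1.0)
    return g


def test_iterative_split_two_level_fixture():
    g = _two_level_fixture()
    res = iterative_split(g, PipelineConfig(), seed=0)
    assert sorted(len(m) for m in res.networks.values()) == [60, 90, 110]
    assert len(res.discarded) == 15
    assert res.oversized == set()
    # the recursion is visible in the trace: root found {200, 60, 15}
    assert res.trace[0]["sizes"] == [200, 60, 15]
    assert res.trace[1]["sizes"] == [110, 90]
    # membership conservation
    members = set().union(*res.networks.values()) | res.discarded
    assert members == set(g.nodes)


def test_single_dense_clique_within_band_is_one_network():
    g = nx.Graph()
    _clique(g, [f"v{i}" for i in range(25)])
    res = iterative_split(g, PipelineConfig(), seed=0)
    assert [len(m) for m in res.networks.values()] == [25]
    assert res.discarded == set()
    assert len(res.trace) == 1   # no recursion


def test_unsplittable_oversized_clique_is_retained_and_flagged():
    g = nx.Graph()
    _clique(g, [f"v{i}" for i in range(130)])
    res = iterative_split(g, PipelineConfig(), seed=0)
    assert [len(m) for m in res.networks.values()] == [130]
    assert len(res.oversized) == 1


def test_too_small_graph_all_discarded():
    g = nx.Graph()
    _clique(g, [f"v{i}" for i in range(10)])
    res = iterative_split(g, PipelineConfig(), seed=0)
    assert res.networks == {}
    assert len(res.discarded) == 10
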