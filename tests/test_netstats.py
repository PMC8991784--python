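"""Network statistics: graph metrics, profile assembly, Spearman matrix."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from physnet import (PipelineConfig, allocate_patients, build_profiles,
                     degree_centrality, edge_density, spearman_matrix,
                     transitivity)
from physnet.cohort import CohortBundle
from physnet.community import NetworkPartition
from physnet.io import ClaimsBundle
from physnet.netstats import profiles_frame
from physnet.sharing import SharingGraph

from oracles import brute_transitivity, spearman_oracle


def _graph(n, edges):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return g


def test_degree_centrality_is_edges_per_vertex():
    assert degree_centrality(_graph(5, [(0, 1), (1, 2), (2, 3), (3, 4),
                                        (4, 0), (0, 2), (1, 3)])) == 1.4
    assert degree_centrality(_graph(3, [])) == 0.0
    assert degree_centrality(nx.complete_graph(4)) == 1.5


def test_edge_density():
    assert edge_density(nx.complete_graph(7)) == pytest.approx(1.0)
    assert edge_density(_graph(5, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0),
                                   (0, 2), (1, 3)])) == pytest.approx(0.7)
    assert edge_density(_graph(4, [])) == 0.0
    assert math.isnan(edge_density(_graph(1, [])))


def test_transitivity_fixtures():
    assert transitivity(nx.complete_graph(3)) == pytest.approx(1.0)
    assert transitivity(_graph(3, [(0, 1), (1, 2)])) == pytest.approx(0.0)
    assert math.isnan(transitivity(_graph(3, [(0, 1)])))


def test_transitivity_matches_brute_force(rng):
    for _ in range(12):
        g = nx.gnp_random_graph(12, 0.35, seed=int(rng.integers(2**31)))
        expected = brute_transitivity(g)
        got = transitivity(g)
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)


# --- hand-built three-network fixture ------------------------------------

def _fixture():
    physicians = pd.DataFrame([
        ("a", "general_practice", "PR1", "R1"),
        ("b", "general_practice", "PR1", "R1"),
        ("c", "gynecology", "PR2", "R1"),
        ("d", "general_practice", "PR3", "R1"),
        ("e", "orthopedics", "PR3", "R1"),
        ("f", "general_practice", "PR4", "R1"),
        ("g", "general_practice", "PR4", "R1"),
        ("h", "general_practice", "PR4", "R1"),
        ("x", "general_practice", "PR5", "R1"),
    ], columns=["physician_id", "specialty_code", "practice_id", "region_code"])

    g = nx.Graph()
    g.add_nodes_from(physicians["physician_id"])
    for a, b, w in [("a", "b", 5), ("b", "c", 3), ("d", "e", 7),
                    ("f", "g", 2), ("g", "h", 2), ("f", "h", 4),
                    ("a", "d", 9)]:
        g.add_edge(a, b, weight=w)
    sharing = SharingGraph(graph=g, panel_size={})

    partition = NetworkPartition(
        assignment={"a": "N1", "b": "N1", "c": "N1", "d": "N2", "e": "N2",
                    "f": "N3", "g": "N3", "h": "N3"},
        networks={"N1": frozenset("abc"), "N2": frozenset("de"),
                  "N3": frozenset("fgh")},
        discarded={"x"})

    cons = pd.DataFrame([
        ("p1", "a", "2016-01-01"), ("p1", "a", "2016-01-08"),
        ("p1", "b", "2016-01-02"), ("p1", "d", "2016-01-03"),
        ("p2", "c", "2016-03-01"), ("p2", "c", "2016-03-02"),
        ("p2", "a", "2016-03-03"),
        ("p3", "d", "2016-04-01"), ("p3", "d", "2016-04-02"),
        ("p3", "d", "2016-04-03"), ("p3", "e", "2016-04-04"),
        ("p4", "f", "2016-05-01"), ("p4", "g", "2016-05-02"),
        ("p4", "x", "2016-05-03"),
        ("p5", "a", "2016-06-01"), ("p5", "d", "2016-06-02"),
    ], columns=["patient_id", "physician_id", "service_date"])
    cons["billing_type_code"] = "consultation"

    cohort = CohortBundle(
        included_physicians=set(physicians["physician_id"]),
        included_patients={"p1", "p2", "p3", "p4", "p5"},
        qualifying_consultations=cons,
        patient_groups={"p1": {7}, "p2": {7, 13}, "p3": {9},
                        "p4": {7}, "p5": {14}})
    bundle = ClaimsBundle(physicians=physicians, patients=pd.DataFrame(),
                          consultations=cons, diagnoses=pd.DataFrame())
    return bundle, cohort, sharing, partition


def test_profiles_match_hand_computation():
    bundle, cohort, sharing, partition = _fixture()
    config = PipelineConfig()
    allocation = allocate_patients(cohort, partition, config)

    alloc = allocation.set_index("patient_id")
    assert alloc.loc["p1", "allocated_network_id"] == "N1"   # 3 of 4 days
    assert alloc.loc["p2", "allocated_network_id"] == "N1"   # 3 of 3
    assert alloc.loc["p3", "allocated_network_id"] == "N2"
    assert alloc.loc["p4", "allocated_network_id"] == "N3"   # 2 of 3
    assert alloc.loc["p5", "allocated_network_id"] == "UNALLOCATED"

    profiles = {p.network_id: p
                for p in build_profiles(partition, allocation, cohort,
                                        sharing, bundle)}
    n1, n2, n3 = profiles["N1"], profiles["N2"], profiles["N3"]

    assert (n1.n_physicians, n1.n_patients) == (3, 2)
    assert (n1.n_specialties, n1.n_practices) == (2, 2)
    assert n1.mean_physicians_per_practice == pytest.approx(1.5)
    assert n1.prop_visits_within == pytest.approx((3 / 4 + 1.0) / 2)
    assert n1.prop_physicians_within == pytest.approx((2 / 3 + 1.0) / 2)
    assert n1.degree_centrality == pytest.approx(2 / 3)
    assert n1.density == pytest.approx(2 / 3)
    assert n1.transitivity == pytest.approx(0.0)
    assert n1.mean_shared_per_edge == pytest.approx(4.0)
    assert n1.mean_degree == pytest.approx(4 / 3)
    assert n1.diagnosis_mix == {7: 1.0, 13: 0.5}
    assert n1.central_physicians == ["b", "a", "c"]   # degree, then id

    assert (n2.n_physicians, n2.n_patients) == (2, 1)
    assert n2.degree_centrality == pytest.approx(0.5)
    assert n2.density == pytest.approx(1.0)
    assert math.isnan(n2.transitivity)
    assert n2.mean_shared_per_edge == pytest.approx(7.0)
    assert n2.prop_visits_within == pytest.approx(1.0)

    assert n3.transitivity == pytest.approx(1.0)
    assert n3.density == pytest.approx(1.0)
    assert n3.degree_centrality == pytest.approx(1.0)
    assert (n3.n_practices, n3.mean_physicians_per_practice) == (1, 3.0)
    assert n3.prop_visits_within == pytest.approx(2 / 3)
    assert n3.specialty_composition == {"general_practice": 1.0}


def test_spearman_identity_and_inverse():
    df = pd.DataFrame({
        "x": [1.0, 2.0, 3.0, 4.0],
        "y": [8.0, 6.0, 4.0, 2.0],
        "z": [1.0, 3.0, 2.0, 5.0],
    })
    rho, pval = spearman_matrix(df, columns=["x", "y", "z"])
    assert rho.loc["x", "x"] == 1.0
    assert rho.loc["x", "y"] == pytest.approx(-1.0)
    assert rho.loc["y", "x"] == rho.loc["x", "y"]


def test_spearman_matches_rank_then_pearson_oracle(rng):
    n = 20
    df = pd.DataFrame({
        "u": rng.normal(size=n),
        "v": rng.integers(0, 5, size=n).astype(float),   # ties
        "w": rng.exponential(size=n),
    })
    df.loc[3, "w"] = np.nan                              # pairwise deletion
    rho, pval = spearman_matrix(df, columns=["u", "v", "w"])
    for a, b in itertools.combinations(["u", "v", "w"], 2):
        sub = df[[a, b]].dropna()
        r_exp, p_exp = spearman_oracle(sub[a], sub[b])
        assert rho.loc[a, b] == pytest.approx(r_exp, abs=1e-12)
        assert pval.loc[a, b] == pytest.approx(p_exp, rel=1e-9)


def test_constant_column_yields_missing():
    df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "c": [2.0] * 5})
    rho, _ = spearman_matrix(df, columns=["x", "c"])
    assert math.isnan(rho.loc["x", "c"])


def test_pipeline_profile_invariants(pipeline_result):
    res = pipeline_result
    df = profiles_frame(res.profiles)
    assert (df["density"].between(0, 1)).all()
    assert df["transitivity"].dropna().between(0, 1).all()
    assert (df["degree_centrality"] >= 0).all()
    # mean degree * V = 2E, i.e. mean_degree = 2 * degree_centrality
    assert np.allclose(df["mean_degree"], 2 * df["degree_centrality"])
    # allocated patients hold strict majorities, so the mean exceeds 0.5
    assert (df["prop_visits_within"] > 0.5).all()
    for p in res.profiles:
        assert sum(p.specialty_composition.values()) == pytest.approx(1.0)
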