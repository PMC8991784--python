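"""Patient-sharing graph construction.

Vertices are cohort physicians; the weight of an edge between two
physicians is the number of *distinct* cohort patients who had at least one
qualifying consultation with both.  An edge is retained only if

* the weight reaches ``min_shared_patients`` (default 20), and
* the shared patients make up at least ``min_relative_share`` (default 5%)
  of the panel of at least one of the two physicians,

where a physician's *panel size* is the number of distinct cohort patients
they treated during the observation year.  Physicians losing all edges stay
in the graph as flagged isolates.

Pairs are enumerated per patient over that patient's distinct physician
set (sum of C(k, 2) incidences, de-duplicated by patient), which is
equivalent to comparing every pair of panels but scales with the data.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import ValidationError
from .io import write_table

log = logging.getLogger(__name__)


@dataclass
class SharingGraph:
    """Weighted undirected physician graph plus panel sizes."""

    graph: nx.Graph                      # edge attribute "weight" = shared patients
    panel_size: dict[str, int]
    isolated: set[str] = field(default_factory=set)

    @property
    def vertices(self) -> set[str]:
        return set(self.graph.nodes)

    def subgraph(self, members) -> nx.Graph:
        return self.graph.subgraph(members)


def count_shared_patients(consultations: pd.DataFrame) -> dict[tuple[str, str], int]:
    """Distinct shared cohort patients for every physician pair.

    Pairs sharing zero patients are absent.  Keys are unordered pairs stored
    with the lexicographically smaller id first.
    """
    pairs = consultations[["patient_id", "physician_id"]].drop_duplicates()
    if not len(pairs):
        return {}
    # integer codes keep the self-merge cheap
    pairs = pairs.copy()
    pairs["phys"] = pairs["physician_id"].astype("category")
    merged = pairs.merge(pairs, on="patient_id")
    mask = merged["phys_x"].cat.codes < merged["phys_y"].cat.codes
    merged = merged.loc[mask]
    counts = (merged.groupby(["physician_id_x", "physician_id_y"], observed=True)
              .size())
    return {(a, b) if a < b else (b, a): int(c)
            for (a, b), c in counts.items()}


def panel_sizes(consultations: pd.DataFrame) -> dict[str, int]:
    """Distinct cohort patients with >= 1 qualifying consultation, per
    physician."""
    pairs = consultations[["patient_id", "physician_id"]].drop_duplicates()
    return pairs.groupby("physician_id").size().to_dict()


def build_graph(shared_counts: dict[tuple[str, str], int],
                panel_size: dict[str, int],
                config: PipelineConfig) -> SharingGraph:
    """Apply the absolute and relative edge thresholds."""
    missing = {p for pair in shared_counts for p in pair} - set(panel_size)
    if missing:
        raise ValidationError(
            f"physicians present in shared counts but missing a panel size: "
            f"{sorted(missing)[:5]}")

    g = nx.Graph()
    g.add_nodes_from(panel_size)
    dropped_abs = dropped_rel = 0
    for (a, b), w in shared_counts.items():
        if w < config.min_shared_patients:
            dropped_abs += 1
            continue
        rel = max(w / panel_size[a], w / panel_size[b])
        if rel < config.min_relative_share:
            dropped_rel += 1
            continue
        g.add_edge(a, b, weight=w)

    isolated = {v for v in g.nodes if g.degree(v) == 0}
    log.info("sharing graph: %d vertices, %d edges retained "
             "(%d below %d shared patients, %d below %.1f%% relative share), "
             "%d isolated physicians",
             g.number_of_nodes(), g.number_of_edges(), dropped_abs,
             config.min_shared_patients, dropped_rel,
             100 * config.min_relative_share, len(isolated))
    return SharingGraph(graph=g, panel_size=dict(panel_size), isolated=isolated)


def build_sharing_graph(consultations: pd.DataFrame,
                        config: PipelineConfig) -> SharingGraph:
    """Convenience: shared-patient counting plus thresholding."""
    return build_graph(count_shared_patients(consultations),
                       panel_sizes(consultations), config)


def write_graph(sharing: SharingGraph, path: str | Path) -> None:
    path = Path(path)
    edges = pd.DataFrame(
        [(a, b, d["weight"]) if a < b else (b, a, d["weight"])
         for a, b, d in sharing.graph.edges(data=True)],
        columns=["physician_a", "physician_b", "shared_patients"],
    ).sort_values(["physician_a", "physician_b"], ignore_index=True)
    write_table(edges, path / "edges.csv")
    panels = pd.DataFrame(sorted(sharing.panel_size.items()),
                          columns=["physician_id", "panel_size"])
    panels["isolated"] = panels["physician_id"].isin(sharing.isolated)
    write_table(panels, path / "panels.csv")
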