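"""Per-network characteristics, graph statistics and rank correlations.

For every retained network the profile row records care-delivery
characteristics (physicians, allocated patients, distinct specialties and
practices, within-network visit shares) and graph statistics on the
intra-network subgraph:

* degree centrality — the network-level ratio E/V of edges to vertices,
* edge density — E / (V(V-1)/2),
* transitivity — the global clustering coefficient,
  3 x triangles / connected triples (unweighted),
* mean shared patients per connected pair and mean degree.

Associations between the profile columns are summarized by pairwise
Spearman rank correlations (average ranks for ties, t-distribution
p-values, pairwise deletion of missing values).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .allocation import UNALLOCATED
from .cohort import CohortBundle
from .community import NetworkPartition
from .io import ClaimsBundle, write_table
from .sharing import SharingGraph

log = logging.getLogger(__name__)

#: default columns of the correlation analysis
CORRELATION_COLUMNS = [
    "n_physicians", "n_patients", "n_specialties", "n_practices",
    "mean_physicians_per_practice", "prop_physicians_within",
    "prop_visits_within", "degree_centrality", "density", "transitivity",
]


def degree_centrality(subgraph: nx.Graph) -> float:
    """Network-level degree centrality: edges per vertex."""
    v = subgraph.number_of_nodes()
    if v < 1:
        raise ValueError("degree centrality needs at least one vertex")
    return subgraph.number_of_edges() / v


def edge_density(subgraph: nx.Graph) -> float:
    """Existing edges over possible edges; NaN (with a warning) if V < 2."""
    v = subgraph.number_of_nodes()
    if v < 2:
        log.warning("edge density undefined for %d vertices", v)
        return float("nan")
    return nx.density(subgraph)


def transitivity(subgraph: nx.Graph) -> float:
    """Global clustering coefficient 3*triangles/triples (unweighted);
    NaN with a warning when the graph has no connected triples."""
    v = subgraph.number_of_nodes()
    triples = sum(d * (d - 1) // 2 for _, d in subgraph.degree())
    if v < 3 or triples == 0:
        log.warning("transitivity undefined: no connected triples")
        return float("nan")
    return nx.transitivity(subgraph)


@dataclass
class NetworkProfile:
    network_id: str
    n_physicians: int
    n_patients: int
    n_specialties: int
    n_practices: int
    mean_physicians_per_practice: float
    prop_physicians_within: float
    prop_visits_within: float
    degree_centrality: float
    density: float
    transitivity: float
    mean_shared_per_edge: float
    mean_degree: float
    specialty_composition: dict[str, float] = field(default_factory=dict)
    diagnosis_mix: dict[int, float] = field(default_factory=dict)
    central_physicians: list[str] = field(default_factory=list)


def _within_proportions(allocation: pd.DataFrame,
                        cohort: CohortBundle,
                        partition: NetworkPartition,
                        ) -> tuple[dict[str, float], dict[str, float]]:
    """Patient-averaged within-network shares of treatment days and of
    distinct physicians consulted, per network."""
    alloc = allocation[allocation["allocated_network_id"] != UNALLOCATED]
    visits_within = alloc.groupby("allocated_network_id")["share"].mean().to_dict()

    cons = cohort.qualifying_consultations
    pairs = cons[["patient_id", "physician_id"]].drop_duplicates()
    pairs = pairs.merge(alloc[["patient_id", "allocated_network_id"]],
                        on="patient_id")
    pairs["in_network"] = (
        pairs["physician_id"].map(partition.assignment)
        == pairs["allocated_network_id"])
    per_patient = pairs.groupby(["allocated_network_id", "patient_id"])[
        "in_network"].mean()
    phys_within = per_patient.groupby(level=0).mean().to_dict()
    return phys_within, visits_within


def build_profiles(partition: NetworkPartition,
                   allocation: pd.DataFrame,
                   cohort: CohortBundle,
                   sharing: SharingGraph,
                   bundle: ClaimsBundle) -> list[NetworkProfile]:
    """One profile row per retained network."""
    phys_info = bundle.physicians.set_index("physician_id")
    phys_within, visits_within = _within_proportions(allocation, cohort, partition)
    alloc = allocation[allocation["allocated_network_id"] != UNALLOCATED]
    patients_of = {nid: set(grp["patient_id"])
                   for nid, grp in alloc.groupby("allocated_network_id")}

    profiles: list[NetworkProfile] = []
    for nid in sorted(partition.networks):
        members = partition.networks[nid]
        sub = sharing.subgraph(members)
        v, e = sub.number_of_nodes(), sub.number_of_edges()
        info = phys_info.loc[sorted(members)]
        n_prac = info["practice_id"].nunique()
        spec_comp = (info["specialty_code"].value_counts(normalize=True)
                     .to_dict())

        pats = patients_of.get(nid, set())
        if not pats:
            log.warning("network %s has zero allocated patients", nid)
        mix: dict[int, float] = {}
        if pats:
            counts: dict[int, int] = {}
            for p in pats:
                for gid in cohort.patient_groups.get(p, ()):
                    counts[gid] = counts.get(gid, 0) + 1
            mix = {g: c / len(pats) for g, c in sorted(counts.items())}

        degs = dict(sub.degree())
        central = sorted(degs, key=lambda p: (-degs[p], p))
        weights = [d["weight"] for _, _, d in sub.edges(data=True)]

        profiles.append(NetworkProfile(
            network_id=nid,
            n_physicians=v,
            n_patients=len(pats),
            n_specialties=info["specialty_code"].nunique(),
            n_practices=n_prac,
            mean_physicians_per_practice=v / n_prac,
            prop_physicians_within=phys_within.get(nid, float("nan")),
            prop_visits_within=visits_within.get(nid, float("nan")),
            degree_centrality=degree_centrality(sub),
            density=edge_density(sub),
            transitivity=transitivity(sub),
            mean_shared_per_edge=float(np.mean(weights)) if weights else float("nan"),
            mean_degree=2.0 * e / v,
            specialty_composition=spec_comp,
            diagnosis_mix=mix,
            central_physicians=central,
        ))
    return profiles


def profiles_frame(profiles: list[NetworkProfile]) -> pd.DataFrame:
    scalar = [
        {k: getattr(p, k) for k in (
            "network_id", "n_physicians", "n_patients", "n_specialties",
            "n_practices", "mean_physicians_per_practice",
            "prop_physicians_within", "prop_visits_within",
            "degree_centrality", "density", "transitivity",
            "mean_shared_per_edge", "mean_degree")}
        for p in profiles
    ]
    return pd.DataFrame(scalar)


def spearman_matrix(profiles: pd.DataFrame | list[NetworkProfile],
                    columns: list[str] | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and p-value matrices over profile columns.

    Ties receive average ranks; p-values use the t-distribution
    approximation; missing values are deleted pairwise; a constant column
    yields NaN against everything (warned).
    """
    df = profiles_frame(profiles) if isinstance(profiles, list) else profiles
    cols = columns or [c for c in CORRELATION_COLUMNS if c in df.columns]
    if len(df) < 4:
        raise ValueError("need at least 4 profiles for a correlation matrix")
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            sub = df[[cols[i], cols[j]]].dropna()
            x, y = sub[cols[i]], sub[cols[j]]
            if len(sub) < 4 or x.nunique() < 2 or y.nunique() < 2:
                log.warning("Spearman undefined for (%s, %s)", cols[i], cols[j])
                r = p = float("nan")
            else:
                r, p = stats.spearmanr(x, y)
            rho.iat[i, j] = rho.iat[j, i] = r
            pval.iat[i, j] = pval.iat[j, i] = p
    return rho, pval


def spearman_long(rho: pd.DataFrame, pval: pd.DataFrame) -> pd.DataFrame:
    rows = []
    cols = list(rho.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            rows.append((a, b, rho.loc[a, b], pval.loc[a, b],
                         bool(pval.loc[a, b] < 0.001)))
    return pd.DataFrame(rows, columns=["var_a", "var_b", "rho", "p",
                                       "significant_0_1pct"])


def central_physician_table(profiles: list[NetworkProfile],
                            bundle: ClaimsBundle,
                            top: int = 3) -> pd.DataFrame:
    spec = bundle.physicians.set_index("physician_id")["specialty_code"]
    rows = []
    for p in profiles:
        for rank, pid in enumerate(p.central_physicians[:top], start=1):
            rows.append((p.network_id, rank, pid, spec.get(pid, "")))
    return pd.DataFrame(rows, columns=["network_id", "rank", "physician_id",
                                       "specialty_code"])


def summary_report(profiles: list[NetworkProfile],
                   allocation: pd.DataFrame,
                   rho: pd.DataFrame, pval: pd.DataFrame) -> str:
    """Human-readable report: network summary plus the correlation matrix."""
    df = profiles_frame(profiles)
    alloc = allocation[allocation["allocated_network_id"] != UNALLOCATED]
    lines = [
        "# Network construction summary", "",
        f"* networks retained: {len(df)}",
        f"* physicians per network: mean {df['n_physicians'].mean():.1f} "
        f"[{df['n_physicians'].min()}; {df['n_physicians'].max()}]",
        f"* patients allocated: {len(alloc)} of {len(allocation)} "
        f"({100 * len(alloc) / max(1, len(allocation)):.1f}%)",
        f"* allocated patients per network: mean {df['n_patients'].mean():.1f} "
        f"[{df['n_patients'].min()}; {df['n_patients'].max()}]",
    ]
    if df["prop_visits_within"].notna().any():
        lines.append(
            f"* within-network visit share (patient-averaged): mean "
            f"{df['prop_visits_within'].mean():.3f} "
            f"[{df['prop_visits_within'].min():.3f}; "
            f"{df['prop_visits_within'].max():.3f}]")
    lines += ["", "## Spearman correlations (p-values)", ""]
    header = "| | " + " | ".join(rho.columns) + " |"
    lines += [header, "|" + "---|" * (len(rho.columns) + 1)]
    for a in rho.index:
        cells = [f"{rho.loc[a, b]:.3f} ({pval.loc[a, b]:.3g})"
                 if a != b else "1" for b in rho.columns]
        lines.append(f"| {a} | " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def write_stats(profiles: list[NetworkProfile],
                allocation: pd.DataFrame,
                bundle: ClaimsBundle,
                path: str | Path) -> None:
    path = Path(path)
    df = profiles_frame(profiles)
    write_table(df, path / "profiles.csv")
    if len(df) >= 4:
        rho, pval = spearman_matrix(df)
        write_table(spearman_long(rho, pval), path / "spearman.csv")
        (path / "summary.md").write_text(
            summary_report(profiles, allocation, rho, pval), encoding="utf-8")
    write_table(central_physician_table(profiles, bundle),
                path / "central_physicians.csv")
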