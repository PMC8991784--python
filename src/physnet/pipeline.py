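"""End-to-end orchestration of the five construction stages."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .allocation import allocate_patients, audit_allocation, write_allocation
from .cohort import CohortBundle, build_cohort
from .community import NetworkPartition, iterative_split, write_partition
from .config import PipelineConfig
from .errors import PhysnetError
from .io import ClaimsBundle, write_table
from .netstats import NetworkProfile, build_profiles, write_stats
from .sharing import SharingGraph, build_sharing_graph, write_graph

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    cohort: CohortBundle
    sharing: SharingGraph
    partition: NetworkPartition
    allocation: pd.DataFrame
    profiles: list[NetworkProfile]


def run_pipeline(bundle: ClaimsBundle, config: PipelineConfig,
                 seed: int | None = None, audit: bool = True) -> PipelineResult:
    """Cohort -> sharing graph -> communities -> allocation -> profiles."""
    cohort = build_cohort(bundle, config)
    if not cohort.included_patients:
        raise PhysnetError(
            "pipeline halted: the cohort is empty after filtering")
    sharing = build_sharing_graph(cohort.qualifying_consultations, config)
    partition = iterative_split(sharing, config, seed=seed)
    allocation = allocate_patients(cohort, partition, config)
    if audit and not audit_allocation(allocation, cohort, partition, config):
        raise PhysnetError("allocation audit failed: an allocated patient "
                           "does not hold a strict majority")
    profiles = build_profiles(partition, allocation, cohort, sharing, bundle)
    return PipelineResult(cohort=cohort, sharing=sharing, partition=partition,
                          allocation=allocation, profiles=profiles)


def write_result(result: PipelineResult, bundle: ClaimsBundle,
                 out: str | Path) -> None:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort(result.cohort, out)
    write_graph(result.sharing, out)
    write_partition(result.partition, out)
    write_allocation(result.allocation, out)
    write_stats(result.profiles, result.allocation, bundle, out)


def write_cohort(cohort: CohortBundle, out: str | Path) -> None:
    out = Path(out)
    write_table(pd.DataFrame({"physician_id": sorted(cohort.included_physicians)}),
                out / "included_physicians.csv")
    rows = [(p, g) for p in sorted(cohort.patient_groups)
            for g in sorted(cohort.patient_groups[p])]
    write_table(pd.DataFrame(rows, columns=["patient_id", "group_id"]),
                out / "patient_groups.csv")
    cons = cohort.qualifying_consultations.sort_values(
        list(cohort.qualifying_consultations.columns), ignore_index=True)
    write_table(cons, out / "qualifying_consultations.csv")
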