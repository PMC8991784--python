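"""Patient allocation to a unique usual provider network.

Each cohort patient is allocated to the network that holds a *strict
majority* (more than ``allocation_majority``, default 50%) of the patient's
treatment days; otherwise the patient stays unallocated.  A treatment day
is a distinct (physician, service date) pair by default
(``day_granularity = physician_day``: two different physicians seen on one
date count as two treatment days); ``calendar_day`` counts distinct dates
instead.  The denominator covers *all* of the patient's qualifying
treatment days, including days spent with physicians who ended up
discarded or isolated and therefore belong to no network.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortBundle
from .community import NetworkPartition
from .config import CALENDAR_DAY, PHYSICIAN_DAY, PipelineConfig
from .io import write_table

log = logging.getLogger(__name__)

UNALLOCATED = "UNALLOCATED"

ALLOCATION_COLUMNS = ["patient_id", "allocated_network_id", "visits_total",
                      "visits_in_allocated", "share"]


def treatment_days(consultations: pd.DataFrame,
                   network_of: dict[str, str],
                   granularity: str = PHYSICIAN_DAY,
                   ) -> tuple[dict[str, int], int]:
    """Treatment days of one patient, split by network.

    Returns (per-network counts, total).  Visits to physicians outside any
    network count toward the total only.
    """
    units = consultations[["physician_id", "service_date"]].drop_duplicates()
    if granularity == CALENDAR_DAY:
        total = units["service_date"].nunique()
        per: dict[str, int] = {}
        nets = units["physician_id"].map(network_of)
        for nid, grp in units.groupby(nets.fillna("")):
            if nid:
                per[nid] = grp["service_date"].nunique()
        return per, int(total)
    per = Counter()
    for _, row in units.iterrows():
        nid = network_of.get(row["physician_id"])
        if nid is not None:
            per[nid] += 1
    return dict(per), len(units)


def allocate_patients(cohort: CohortBundle,
                      partition: NetworkPartition,
                      config: PipelineConfig) -> pd.DataFrame:
    """Allocate every cohort patient (table with one row per patient)."""
    cons = cohort.qualifying_consultations
    units = cons[["patient_id", "physician_id", "service_date"]].drop_duplicates()
    units = units.assign(
        network_id=units["physician_id"].map(partition.assignment))

    if config.day_granularity == CALENDAR_DAY:
        total = units.groupby("patient_id")["service_date"].nunique()
        in_net = (units.dropna(subset=["network_id"])
                  .groupby(["patient_id", "network_id"])["service_date"]
                  .nunique())
    else:
        total = units.groupby("patient_id").size()
        in_net = (units.dropna(subset=["network_id"])
                  .groupby(["patient_id", "network_id"]).size())

    rows = []
    per_patient = in_net.groupby(level="patient_id")
    best = per_patient.max()
    # ties cannot both exceed a strict majority, so idxmax is safe for winners
    best_net = {p: n for (p, n) in per_patient.idxmax().values} \
        if len(in_net) else {}

    for pid in sorted(set(cohort.included_patients) | set(total.index)):
        t = int(total.get(pid, 0))
        if t == 0:
            log.warning("patient %s has no qualifying treatment days; "
                        "left unallocated", pid)
            rows.append((pid, UNALLOCATED, 0, 0, np.nan))
            continue
        b = int(best.get(pid, 0))
        if b > config.allocation_majority * t:
            rows.append((pid, best_net[pid], t, b, b / t))
        else:
            rows.append((pid, UNALLOCATED, t, b, b / t if t else np.nan))

    table = pd.DataFrame(rows, columns=ALLOCATION_COLUMNS)
    n_alloc = int((table["allocated_network_id"] != UNALLOCATED).sum())
    log.info("allocation: %d of %d patients allocated (%.1f%%)",
             n_alloc, len(table), 100 * n_alloc / max(1, len(table)))
    return table


def audit_allocation(allocation: pd.DataFrame,
                     cohort: CohortBundle,
                     partition: NetworkPartition,
                     config: PipelineConfig) -> bool:
    """Independent recount: every allocated patient's share must exceed the
    majority threshold when recomputed from raw consultations."""
    cons = cohort.qualifying_consultations
    by_patient = dict(tuple(cons.groupby("patient_id")))
    ok = True
    for _, row in allocation.iterrows():
        if row["allocated_network_id"] == UNALLOCATED:
            continue
        per, tot = treatment_days(by_patient[row["patient_id"]],
                                  partition.assignment,
                                  config.day_granularity)
        share = per.get(row["allocated_network_id"], 0) / tot
        if not share > config.allocation_majority:
            log.error("allocation audit failed for patient %s: share %.3f",
                      row["patient_id"], share)
            ok = False
    return ok


def write_allocation(allocation: pd.DataFrame, path: str | Path) -> None:
    out = allocation.sort_values("patient_id", ignore_index=True)
    write_table(out, Path(path) / "allocation.csv")
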