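"""Cohort construction: physician, patient and consultation filters.

Three restrictions turn a raw claims bundle into the analysis cohort:

1. physicians of predefined specialties with little or no face-to-face
   patient contact (laboratory medicine, radiology, pathology, ...) are
   excluded, as are physicians outside the configured regions;
2. patients qualify only if they belong to at least one of the 14
   ambulatory-care-sensitive diagnosis groups under the M1Q/M2Q frequency
   rules and diagnosis-certainty qualifiers (see :mod:`physnet.catalog`);
   dialysis patients and patients below the minimum age are removed;
3. consultations with excluded billing service types (laboratory referrals,
   emergency contacts, ...) are dropped; only consultations linking an
   included physician with an included patient remain.

Patients left without any qualifying consultation are dropped from the
cohort at the end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import DEFAULT_CATALOG, M2Q, QUALIFIERS, DiagnosisGroupRule
from .config import PipelineConfig
from .errors import ValidationError
from .io import ClaimsBundle

log = logging.getLogger(__name__)


@dataclass
class CohortBundle:
    """Filtered views defining the analysis cohort."""

    included_physicians: set[str]
    included_patients: set[str]
    qualifying_consultations: pd.DataFrame
    patient_groups: dict[str, set[int]]


def filter_physicians(bundle: ClaimsBundle, config: PipelineConfig) -> set[str]:
    """Physicians whose specialty is not excluded (and, if configured,
    whose region is allowed)."""
    phys = bundle.physicians
    keep = ~phys["specialty_code"].isin(config.excluded_specialties)
    if config.allowed_regions is not None:
        keep &= phys["region_code"].isin(config.allowed_regions)
    kept = set(phys.loc[keep, "physician_id"])
    log.info("physician filter: %d of %d retained", len(kept), len(phys))
    if not kept:
        log.warning("physician filter removed every physician")
    return kept


def _check_qualifiers(qualifier: pd.Series) -> None:
    bad = qualifier.index[~qualifier.isin(QUALIFIERS)]
    if len(bad):
        raise ValidationError(
            "unknown diagnosis qualifier label(s)",
            [(int(i), repr(qualifier[i])) for i in bad])


def classify_patients(diagnoses: pd.DataFrame,
                      catalog: Sequence[DiagnosisGroupRule] = DEFAULT_CATALOG,
                      ) -> dict[str, set[int]]:
    """Map each patient to the set of (merged) diagnosis groups they satisfy.

    Group membership requires records matching the rule's ICD prefixes and
    accepted qualifiers in >= 2 distinct quarters (M2Q) or >= 1 quarter
    (M1Q).  Patients satisfying no rule are absent from the result.
    """
    _check_qualifiers(diagnoses["qualifier"])
    out: dict[str, set[int]] = {}
    if not len(diagnoses):
        return out
    codes = diagnoses["icd10_code"].astype(str)
    for rule in catalog:
        mask = diagnoses["qualifier"].isin(rule.accepted_qualifiers)
        code_mask = np.zeros(len(diagnoses), dtype=bool)
        for prefix in rule.icd10_prefixes:
            code_mask |= codes.str.startswith(prefix).to_numpy()
        sub = diagnoses.loc[mask.to_numpy() & code_mask, ["patient_id", "quarter"]]
        if not len(sub):
            continue
        nq = sub.groupby("patient_id", sort=False)["quarter"].nunique()
        need = 2 if rule.frequency_rule == M2Q else 1
        for pid in nq.index[nq >= need]:
            out.setdefault(pid, set()).add(rule.group_id)
    return out


def classify_patient(records: Iterable[tuple[str, int, str]],
                     catalog: Sequence[DiagnosisGroupRule] = DEFAULT_CATALOG,
                     ) -> set[int]:
    """Classify one patient from (icd10_code, quarter, qualifier) records."""
    rows = list(records)
    df = pd.DataFrame(rows, columns=["icd10_code", "quarter", "qualifier"])
    df["patient_id"] = "p"
    return classify_patients(df, catalog).get("p", set())


def filter_consultations(bundle: ClaimsBundle,
                         included_physicians: set[str],
                         included_patients: set[str],
                         config: PipelineConfig) -> pd.DataFrame:
    """Keep consultations with allowed billing types between included
    physicians and included patients."""
    cons = bundle.consultations
    keep = (~cons["billing_type_code"].isin(config.excluded_billing_types)
            & cons["physician_id"].isin(included_physicians)
            & cons["patient_id"].isin(included_patients))
    kept = cons.loc[keep].reset_index(drop=True)
    log.info("consultation filter: %d of %d retained (%d billing-excluded)",
             len(kept), len(cons),
             int(cons["billing_type_code"].isin(config.excluded_billing_types).sum()))
    return kept


def _dialysis_patients(bundle: ClaimsBundle, config: PipelineConfig) -> set[str]:
    cons = bundle.consultations
    mask = cons["billing_type_code"].isin(config.dialysis_billing_types)
    return set(cons.loc[mask, "patient_id"])


def _underage_patients(bundle: ClaimsBundle, config: PipelineConfig) -> set[str]:
    if config.min_patient_age <= 0:
        return set()
    year = config.observation_year
    if year is None:
        dates = pd.to_datetime(bundle.consultations["service_date"],
                               format="ISO8601", errors="coerce")
        if dates.notna().any():
            year = int(dates.dt.year.min())
        else:
            return set()
    age = year - bundle.patients["birth_year"].astype(int)
    return set(bundle.patients.loc[(age < config.min_patient_age).to_numpy(),
                                   "patient_id"])


def build_cohort(bundle: ClaimsBundle, config: PipelineConfig) -> CohortBundle:
    """Compose the physician, patient and consultation filters."""
    included_physicians = filter_physicians(bundle, config)

    groups = classify_patients(bundle.diagnoses, config.diagnosis_catalog)
    qualified = set(groups)
    dialysis = _dialysis_patients(bundle, config)
    underage = _underage_patients(bundle, config)
    included_patients = qualified - dialysis - underage
    log.info("patient filter: %d qualified by diagnosis, %d dialysis-excluded,"
             " %d below age %d", len(qualified), len(qualified & dialysis),
             len(qualified & underage), config.min_patient_age)

    consultations = filter_consultations(
        bundle, included_physicians, included_patients, config)
    # dialysis-billed contacts are not face-to-face visits either
    consultations = consultations[
        ~consultations["billing_type_code"].isin(config.dialysis_billing_types)
    ].reset_index(drop=True)

    with_visit = set(consultations["patient_id"])
    dropped = len(included_patients) - len(included_patients & with_visit)
    included_patients &= with_visit
    if dropped:
        log.info("dropped %d patients without qualifying consultations", dropped)
    consultations = consultations[
        consultations["patient_id"].isin(included_patients)].reset_index(drop=True)

    if not included_patients:
        log.warning("cohort is empty: no patient satisfies the inclusion rules")

    return CohortBundle(
        included_physicians=included_physicians,
        included_patients=included_patients,
        qualifying_consultations=consultations,
        patient_groups={p: g for p, g in groups.items() if p in included_patients},
    )
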