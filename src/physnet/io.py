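"""Typed CSV I/O for the claims bundle and pipeline products.

The bundle is four linked tables (UTF-8, comma-separated, RFC 4180, header
row required):

``physicians.csv``     physician_id, specialty_code, practice_id, region_code
``patients.csv``       patient_id, birth_year, gender
``consultations.csv``  patient_id, physician_id, service_date (ISO-8601),
                       billing_type_code
``diagnoses.csv``      patient_id, icd10_code, quarter (1-4), qualifier
                       (confirmed | status_post | other)

All ids are opaque strings.  ``read_bundle`` validates referential
integrity, id uniqueness and enumerations and raises
:class:`~physnet.errors.ValidationError` with row-level diagnostics on
violation.  If a diagnoses file lacks the ``quarter`` column but carries a
``service_date``, quarters are derived from the date (months 1-3 -> Q1, ...,
10-12 -> Q4), mirroring quarter-resolved ambulatory claims.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .catalog import QUALIFIERS
from .errors import ValidationError

log = logging.getLogger(__name__)

PHYSICIAN_COLUMNS = ["physician_id", "specialty_code", "practice_id", "region_code"]
PATIENT_COLUMNS = ["patient_id", "birth_year", "gender"]
CONSULTATION_COLUMNS = ["patient_id", "physician_id", "service_date", "billing_type_code"]
DIAGNOSIS_COLUMNS = ["patient_id", "icd10_code", "quarter", "qualifier"]

_FILES = {
    "physicians": PHYSICIAN_COLUMNS,
    "patients": PATIENT_COLUMNS,
    "consultations": CONSULTATION_COLUMNS,
    "diagnoses": DIAGNOSIS_COLUMNS,
}


@dataclass
class ClaimsBundle:
    """The four linked claims tables every pipeline stage consumes."""

    physicians: pd.DataFrame
    patients: pd.DataFrame
    consultations: pd.DataFrame
    diagnoses: pd.DataFrame

    def validate(self) -> "ClaimsBundle":
        _check_columns(self)
        problems: list[tuple[int, str]] = []

        for table, col in (("physicians", "physician_id"), ("patients", "patient_id")):
            df = getattr(self, table)
            dup = df[df[col].duplicated(keep=False)]
            problems += [(int(i), f"duplicate {col} {v!r} in {table}")
                         for i, v in dup[col].items()]

        known_phys = set(self.physicians["physician_id"])
        known_pat = set(self.patients["patient_id"])
        for i, v in self.consultations["physician_id"].items():
            if v not in known_phys:
                problems.append((int(i), f"consultation references unknown physician {v!r}"))
        for table in ("consultations", "diagnoses"):
            for i, v in getattr(self, table)["patient_id"].items():
                if v not in known_pat:
                    problems.append((int(i), f"{table} row references unknown patient {v!r}"))

        q = pd.to_numeric(self.diagnoses["quarter"], errors="coerce")
        bad_q = self.diagnoses.index[~q.isin([1, 2, 3, 4])]
        problems += [(int(i), f"quarter {self.diagnoses.at[i, 'quarter']!r} not in 1..4")
                     for i in bad_q]

        bad_qual = self.diagnoses.index[~self.diagnoses["qualifier"].isin(QUALIFIERS)]
        problems += [(int(i), f"unknown qualifier {self.diagnoses.at[i, 'qualifier']!r}")
                     for i in bad_qual]

        dates = pd.to_datetime(self.consultations["service_date"], errors="coerce",
                               format="ISO8601")
        problems += [(int(i), "unparseable service_date")
                     for i in self.consultations.index[dates.isna()]]

        if problems:
            problems.sort()
            raise ValidationError("claims bundle failed validation", problems)
        return self

    def normalized(self) -> "ClaimsBundle":
        """Return a copy with canonical column order, dtypes and row order."""
        b = ClaimsBundle(
            physicians=self.physicians[PHYSICIAN_COLUMNS].astype(
                {c: str for c in PHYSICIAN_COLUMNS}),
            patients=self.patients[PATIENT_COLUMNS].astype(
                {"patient_id": str, "birth_year": int, "gender": str}),
            consultations=self.consultations[CONSULTATION_COLUMNS].astype(
                {c: str for c in CONSULTATION_COLUMNS}),
            diagnoses=self.diagnoses[DIAGNOSIS_COLUMNS].astype(
                {"patient_id": str, "icd10_code": str, "quarter": int,
                 "qualifier": str}),
        )
        b.physicians = b.physicians.sort_values("physician_id", kind="stable",
                                                ignore_index=True)
        b.patients = b.patients.sort_values("patient_id", kind="stable",
                                            ignore_index=True)
        b.consultations = b.consultations.sort_values(
            CONSULTATION_COLUMNS, kind="stable", ignore_index=True)
        b.diagnoses = b.diagnoses.sort_values(
            ["patient_id", "icd10_code", "quarter", "qualifier"],
            kind="stable", ignore_index=True)
        return b


def _check_columns(bundle: ClaimsBundle) -> None:
    for table, cols in _FILES.items():
        df = getattr(bundle, table)
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValidationError(
                f"table {table!r} is missing column(s) {sorted(missing)}")


def quarter_from_date(dates: pd.Series) -> pd.Series:
    """Map service dates to calendar quarters 1-4."""
    parsed = pd.to_datetime(dates, format="ISO8601")
    return ((parsed.dt.month - 1) // 3 + 1).astype(int)


def read_bundle(path: str | Path) -> ClaimsBundle:
    """Read and validate the four claims CSVs from a directory."""
    path = Path(path)
    tables: dict[str, pd.DataFrame] = {}
    for name, cols in _FILES.items():
        f = path / f"{name}.csv"
        if not f.exists():
            raise FileNotFoundError(f"missing claims table {f}")
        tables[name] = pd.read_csv(f, dtype=str, keep_default_na=False)
        log.info("read %s: %d rows", f.name, len(tables[name]))

    diag = tables["diagnoses"]
    if "quarter" not in diag.columns and "service_date" in diag.columns:
        diag = diag.assign(quarter=quarter_from_date(diag["service_date"]))
        tables["diagnoses"] = diag

    bundle = ClaimsBundle(**tables)
    _check_columns(bundle)
    bundle.validate()
    return bundle.normalized()


def write_bundle(bundle: ClaimsBundle, path: str | Path) -> None:
    """Write the four claims CSVs (canonical order, so output is stable)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    b = bundle.normalized()
    for name in _FILES:
        f = path / f"{name}.csv"
        getattr(b, name).to_csv(f, index=False)
        log.info("wrote %s: %d rows", f.name, len(getattr(b, name)))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    log.info("wrote %s: %d rows", Path(path).name, len(df))
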