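"""Pipeline configuration.

All thresholds of the network-construction procedure live here with their
standard defaults: an edge between two physicians requires at least 20
distinct shared patients AND those patients must make up at least 5% of the
panel of at least one of the two physicians; retained networks must have
between 20 and 120 physicians; a patient is allocated to the network holding
a strict majority (>50%) of their treatment days.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .catalog import DEFAULT_CATALOG, DiagnosisGroupRule
from .errors import ConfigError

#: physician specialties excluded from network construction (limited or no
#: face-to-face patient contact, or not caring for the adult ACSC cohort)
DEFAULT_EXCLUDED_SPECIALTIES = frozenset({
    "pediatrics",
    "laboratory_medicine",
    "microbiology",
    "oral_maxillofacial_surgery",
    "pathology",
    "radiology",
    "radiation_therapy",
    "transfusion_medicine",
})

#: billing service types that do not represent a regular face-to-face visit
DEFAULT_EXCLUDED_BILLING_TYPES = frozenset({
    "lab_referral",
    "lab_community_request",
    "emergency",
    "emergency_service",
    "emergency_taxi",
    "rescue_service",
    "central_emergency_service",
    "holiday_replacement",
})

#: billing codes identifying dialysis treatment; any patient with such a
#: consultation is excluded from the cohort entirely
DEFAULT_DIALYSIS_BILLING_TYPES = frozenset({"dialysis"})

PHYSICIAN_DAY = "physician_day"
CALENDAR_DAY = "calendar_day"


@dataclass(frozen=True)
class PipelineConfig:
    min_shared_patients: int = 20
    min_relative_share: float = 0.05
    min_network_size: int = 20
    max_network_size: int = 120
    allocation_majority: float = 0.5          # strict: share must EXCEED this
    min_patient_age: int = 18
    day_granularity: str = PHYSICIAN_DAY
    excluded_specialties: frozenset[str] = DEFAULT_EXCLUDED_SPECIALTIES
    excluded_billing_types: frozenset[str] = DEFAULT_EXCLUDED_BILLING_TYPES
    dialysis_billing_types: frozenset[str] = DEFAULT_DIALYSIS_BILLING_TYPES
    allowed_regions: frozenset[str] | None = None
    observation_year: int | None = None
    diagnosis_catalog: tuple[DiagnosisGroupRule, ...] = DEFAULT_CATALOG
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_shared_patients < 0:
            raise ConfigError("min_shared_patients must be >= 0")
        if not 0 < self.min_relative_share < 1:
            raise ConfigError("min_relative_share must lie strictly in (0, 1)")
        if self.min_network_size > self.max_network_size:
            raise ConfigError("min_network_size must not exceed max_network_size")
        if self.min_network_size < 1:
            raise ConfigError("min_network_size must be >= 1")
        if not 0 < self.allocation_majority < 1:
            raise ConfigError("allocation_majority must lie strictly in (0, 1)")
        if self.day_granularity not in (PHYSICIAN_DAY, CALENDAR_DAY):
            raise ConfigError(
                f"day_granularity must be {PHYSICIAN_DAY!r} or {CALENDAR_DAY!r}")
        if self.min_patient_age < 0:
            raise ConfigError("min_patient_age must be >= 0")


_SET_FIELDS = {"excluded_specialties", "excluded_billing_types",
               "dialysis_billing_types", "allowed_regions"}


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML key-value file.

    Unspecified keys take the defaults above; an unknown key raises
    :class:`ConfigError`.  Keyword overrides are applied on top of the file.
    """
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must be a mapping")
        values.update(raw)
    values.update(overrides)

    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(values) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    for key in _SET_FIELDS & set(values):
        if values[key] is not None:
            values[key] = frozenset(values[key])
    return PipelineConfig(**values)
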