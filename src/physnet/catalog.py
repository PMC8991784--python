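"""Catalog of ambulatory care-sensitive diagnosis groups.

The cohort is defined by 14 diagnosis groups of ambulatory care-sensitive
conditions (ACSC) coded in ICD-10.  Each group carries

* a list of ICD-10 code prefixes (a prefix such as ``I10`` matches ``I10``,
  ``I10.0``, ``I10.90``; the 4-digit prefix ``R07.0`` matches only
  ``R07.0``-prefixed codes),
* a frequency rule — ``M1Q`` (coded in at least one quarter of the
  observation year) for the more acute conditions, ``M2Q`` (coded in at
  least two *distinct* quarters) for the chronic ones, and
* a qualifier rule restricting which diagnosis-certainty labels count:
  ``confirmed_only``, ``confirmed_or_status_post`` or ``status_post_only``.

Two groups have sub-rules with different ICD lists and qualifier rules
(ischemic heart disease 1a/1b and bronchitis/COPD 4a/4b); they are evaluated
separately but reported under their merged group id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

M1Q = "M1Q"
M2Q = "M2Q"

CONFIRMED_ONLY = "confirmed_only"
CONFIRMED_OR_STATUS_POST = "confirmed_or_status_post"
STATUS_POST_ONLY = "status_post_only"

#: diagnosis-certainty labels accepted in the diagnoses table
QUALIFIERS = ("confirmed", "status_post", "other")

_ACCEPTED = {
    CONFIRMED_ONLY: frozenset({"confirmed"}),
    CONFIRMED_OR_STATUS_POST: frozenset({"confirmed", "status_post"}),
    STATUS_POST_ONLY: frozenset({"status_post"}),
}


def expand_icd_range(spec: str) -> list[str]:
    """Expand a range such as ``"I10-I15"`` into the inclusive list of
    3-character codes; a plain code is returned as a singleton list."""
    if "-" not in spec:
        return [spec]
    lo, hi = spec.split("-")
    if lo[0] != hi[0] or len(lo) != 3 or len(hi) != 3:
        raise ValueError(f"unsupported ICD range {spec!r}")
    letter = lo[0]
    return [f"{letter}{n:02d}" for n in range(int(lo[1:]), int(hi[1:]) + 1)]


def _codes(*specs: str) -> tuple[str, ...]:
    out: list[str] = []
    for s in specs:
        out.extend(expand_icd_range(s))
    return tuple(out)


@dataclass(frozen=True)
class DiagnosisGroupRule:
    """One (sub-)rule of the ACSC catalog."""

    rule_id: str                    # "1a", "1b", "2", ... "14"
    group_id: int                   # merged reporting group, 1..14
    name: str
    icd10_prefixes: tuple[str, ...]
    frequency_rule: str             # M1Q | M2Q
    qualifier_rule: str

    def __post_init__(self) -> None:
        if self.frequency_rule not in (M1Q, M2Q):
            raise ValueError(f"bad frequency_rule {self.frequency_rule!r}")
        if self.qualifier_rule not in _ACCEPTED:
            raise ValueError(f"bad qualifier_rule {self.qualifier_rule!r}")

    @property
    def accepted_qualifiers(self) -> frozenset[str]:
        return _ACCEPTED[self.qualifier_rule]

    def matches_code(self, code: str) -> bool:
        return any(code.startswith(p) for p in self.icd10_prefixes)


DEFAULT_CATALOG: tuple[DiagnosisGroupRule, ...] = (
    DiagnosisGroupRule("1a", 1, "Ischemic heart diseases",
                       _codes("I20", "I25"), M2Q, CONFIRMED_OR_STATUS_POST),
    DiagnosisGroupRule("1b", 1, "Ischemic heart diseases",
                       _codes("I21", "I22", "I23", "I24"), M2Q, STATUS_POST_ONLY),
    DiagnosisGroupRule("2", 2, "Heart failure",
                       _codes("I50"), M2Q, CONFIRMED_OR_STATUS_POST),
    DiagnosisGroupRule("3", 3, "Other diseases of the circulatory system",
                       _codes("I05", "I06", "I07", "I09", "I08", "I49", "I48",
                              "I67", "I70", "I73", "I78", "I80", "I83", "I86",
                              "I87", "I95", "R00", "I42", "I74"),
                       M2Q, CONFIRMED_OR_STATUS_POST),
    DiagnosisGroupRule("4a", 4, "Bronchitis",
                       _codes("J20", "J21", "J22", "J40", "J41", "J42", "J43"),
                       M1Q, CONFIRMED_ONLY),
    DiagnosisGroupRule("4b", 4, "COPD",
                       _codes("J44", "J47"), M2Q, CONFIRMED_OR_STATUS_POST),
    DiagnosisGroupRule("5", 5, "Mental/behavioral disorders due to alcohol or opioids",
                       _codes("F10", "F11"), M2Q, CONFIRMED_OR_STATUS_POST),
    DiagnosisGroupRule("6", 6, "Back pain [dorsopathies]",
                       _codes("M42", "M47", "M53", "M54", "M50", "M51"),
                       M2Q, CONFIRMED_OR_STATUS_POST),
    DiagnosisGroupRule("7", 7, "Hypertension",
                       _codes("I10-I15"), M2Q, CONFIRMED_OR_STATUS_POST),
    DiagnosisGroupRule("8", 8, "Gastroenteritis and other intestinal diseases",
                       _codes("K52", "K57", "K58", "K59"), M1Q, CONFIRMED_ONLY),
    DiagnosisGroupRule("9", 9, "Intestinal infectious diseases",
                       _codes("A00-A09"), M1Q, CONFIRMED_ONLY),
    DiagnosisGroupRule("10", 10, "Influenza and pneumonia",
                       _codes("J10", "J11", "J13", "J14", "J15", "J16", "J18", "J12"),
                       M1Q, CONFIRMED_ONLY),
    DiagnosisGroupRule("11", 11, "Ear, nose, and throat infections",
                       _codes("H66", "J01-J03", "J06", "J31", "J32", "J35",
                              "H65", "H73", "J04", "R07.0"),
                       M1Q, CONFIRMED_ONLY),
    DiagnosisGroupRule("12", 12, "Depressive disorders",
                       _codes("F32", "F33"), M2Q, CONFIRMED_OR_STATUS_POST),
    DiagnosisGroupRule("13", 13, "Diabetes mellitus",
                       _codes("E10", "E11", "E13", "E14", "E16"),
                       M2Q, CONFIRMED_OR_STATUS_POST),
    DiagnosisGroupRule("14", 14, "Gonarthrosis",
                       _codes("M17"), M2Q, CONFIRMED_OR_STATUS_POST),
)

#: merged reporting groups, in catalog order
GROUP_IDS: tuple[int, ...] = tuple(sorted({r.group_id for r in DEFAULT_CATALOG}))

GROUP_NAMES: dict[int, str] = {
    1: "Ischemic heart diseases",
    2: "Heart failure",
    3: "Other diseases of the circulatory system",
    4: "Bronchitis/COPD",
    5: "Mental/behavioral disorders due to alcohol or opioids",
    6: "Back pain [dorsopathies]",
    7: "Hypertension",
    8: "Gastroenteritis and other intestinal diseases",
    9: "Intestinal infectious diseases",
    10: "Influenza and pneumonia",
    11: "Ear, nose, and throat infections",
    12: "Depressive disorders",
    13: "Diabetes mellitus",
    14: "Gonarthrosis",
}

#: observed relative frequency (%) of each merged group in a large claims
#: population before allocation; used as sampling weights by the generator
GROUP_PREVALENCE_PCT: dict[int, float] = {
    1: 10, 2: 4, 3: 25, 4: 24, 5: 2, 6: 35, 7: 42,
    8: 15, 9: 12, 10: 3, 11: 39, 12: 16, 13: 15, 14: 9,
}

def rules_for_group(group_id: int,
                    catalog: Sequence[DiagnosisGroupRule] = DEFAULT_CATALOG
                    ) -> list[DiagnosisGroupRule]:
    return [r for r in catalog if r.group_id == group_id]
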