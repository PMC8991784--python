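"""Synthetic ambulatory-claims generator with planted physician communities.

Real statutory-health-insurance billing data are access-restricted, so the
pipeline is exercised on synthetic claims bundles whose ground truth is
known by construction:

* physicians are partitioned into *planted communities*; practices never
  span communities;
* every patient has a *home community* and directs each consultation to a
  physician of that community with probability
  ``within_community_visit_prob`` (otherwise to a uniformly random other
  community) — patient sharing therefore concentrates within the planted
  blocks and the sharing graph carries a recoverable community signal;
* a configurable share of patients is generated to satisfy the
  ambulatory-care-sensitive cohort rules (M1Q/M2Q over the 14 diagnosis
  groups), the rest receive only non-qualifying diagnosis records;
* a share of physicians carries excluded specialties and a share of
  consultations carries excluded billing codes, so the cohort filters have
  real work to do.

Everything is drawn from a single :class:`numpy.random.Generator`, so a
fixed seed reproduces the bundle exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import catalog
from .catalog import DEFAULT_CATALOG, GROUP_PREVALENCE_PCT, M2Q, rules_for_group
from .config import DEFAULT_EXCLUDED_SPECIALTIES
from .errors import ConfigError
from .io import ClaimsBundle, write_bundle, write_table

#: specialty mix of included (network-eligible) physicians; general
#: practitioners dominate ambulatory care with ~45% of network physicians
DEFAULT_SPECIALTY_DISTRIBUTION: dict[str, float] = {
    "general_practice": 0.45,
    "gynecology": 0.10,
    "internal_medicine": 0.08,
    "orthopedics": 0.05,
    "ophthalmology": 0.05,
    "dermatology": 0.05,
    "ent": 0.05,
    "neurology": 0.04,
    "urology": 0.04,
    "surgery": 0.04,
    "cardiology": 0.03,
    "psychiatry": 0.02,
}

#: ICD codes outside the ACSC catalog, used for non-qualifying noise records
_NON_CATALOG_CODES = ("Z00", "K21", "N39", "L20", "H52", "B01")

#: excluded billing codes actually emitted by the generator
_EXCLUDED_BILLING_SAMPLE = ("emergency", "lab_referral")

_INCLUDED_BILLING = "consultation"
_DIALYSIS_BILLING = "dialysis"


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults emulate a one-year regional extract."""

    n_physicians: int = 120
    n_practices: int = 60
    n_patients: int = 4000
    n_planted_communities: int = 4
    within_community_visit_prob: float = 0.9
    specialty_distribution: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECIALTY_DISTRIBUTION))
    mean_diseases_per_patient: float = 2.5
    female_share: float = 0.55
    mean_age: float = 54.0
    age_sd: float = 18.0
    quarters: int = 4
    observation_year: int = 2016
    mean_visits: float = 10.0
    visit_dispersion: float = 2.0
    noncohort_share: float = 0.30
    excluded_specialty_share: float = 0.08
    excluded_billing_share: float = 0.05
    dialysis_share: float = 0.01
    region_code: str = "R1"
    community_sizes: Sequence[int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_physicians", "n_practices", "n_patients",
                     "n_planted_communities"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be a positive count")
        for name in ("within_community_visit_prob", "female_share",
                     "noncohort_share", "excluded_specialty_share",
                     "excluded_billing_share", "dialysis_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1]")
        if self.mean_diseases_per_patient <= 0:
            raise ConfigError("mean_diseases_per_patient must be positive")
        if self.mean_visits <= 0:
            raise ConfigError("mean_visits must be positive")
        if self.visit_dispersion <= 0:
            raise ConfigError("visit_dispersion must be positive")
        if not 2 <= self.quarters <= 4:
            raise ConfigError("quarters must be between 2 and 4")
        total = float(sum(self.specialty_distribution.values()))
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"specialty_distribution probabilities sum to {total}, not 1")
        if self.within_community_visit_prob < 1.0 / self.n_planted_communities:
            raise ConfigError(
                "within_community_visit_prob below 1/n_planted_communities: "
                "no planted signal")
        if self.community_sizes is not None:
            sizes = list(self.community_sizes)
            if len(sizes) != self.n_planted_communities:
                raise ConfigError(
                    "community_sizes must have n_planted_communities entries")
            if sum(sizes) != self.n_physicians:
                raise ConfigError("community_sizes must sum to n_physicians")
            if min(sizes) < 1:
                raise ConfigError("community_sizes entries must be positive")
        if self.n_planted_communities > self.n_physicians:
            raise ConfigError("n_planted_communities exceeds n_physicians")


@dataclass
class GroundTruth:
    """Planted labels enabling recovery tests downstream."""

    physician_community: dict[str, int]
    patient_home_community: dict[str, int]
    cohort_flag: dict[str, bool]        # generated to satisfy the cohort rules
    dialysis_flag: dict[str, bool]


def _community_sizes(config: SimConfig) -> np.ndarray:
    if config.community_sizes is not None:
        return np.asarray(list(config.community_sizes), dtype=int)
    k, n = config.n_planted_communities, config.n_physicians
    sizes = np.full(k, n // k, dtype=int)
    sizes[: n % k] += 1
    return sizes


def _zero_truncated_poisson(rng: np.random.Generator, mean: float,
                            size: int) -> np.ndarray:
    """Sample a zero-truncated Poisson whose *truncated* mean equals ``mean``."""
    from scipy.optimize import brentq

    if mean <= 1.0 + 1e-12:
        return np.ones(size, dtype=int)
    lam = brentq(lambda l: l / (1.0 - np.exp(-l)) - mean, 1e-9, mean)
    draws = rng.poisson(lam, size=size)
    while (zeros := draws == 0).any():
        draws[zeros] = rng.poisson(lam, size=int(zeros.sum()))
    return draws


def _sample_icd_codes(rng: np.random.Generator, rule_idx: np.ndarray,
                      catalog_rules: Sequence) -> np.ndarray:
    """Uniform ICD prefix per record from each record's rule; a random
    4th-digit suffix is appended to ~30% of 3-character codes so that
    prefix matching is exercised downstream."""
    codes = np.empty(len(rule_idx), dtype=object)
    for ri, rule in enumerate(catalog_rules):   # catalog order => deterministic
        mask = rule_idx == ri
        m = int(mask.sum())
        if m == 0:
            continue
        prefixes = np.asarray(rule.icd10_prefixes, dtype=object)
        codes[mask] = prefixes[rng.integers(0, len(prefixes), size=m)]
    suffix = rng.random(len(codes)) < 0.3
    digit = rng.integers(0, 10, size=len(codes))
    out = [
        f"{c}.{d}" if s and "." not in c else c
        for c, s, d in zip(codes, suffix, digit)
    ]
    return np.asarray(out, dtype=object)


def _generate_physicians(rng, config, sizes):
    n = config.n_physicians
    ids = np.array([f"P{i:05d}" for i in range(n)], dtype=object)
    community = np.repeat(np.arange(len(sizes)), sizes)

    specialty = np.empty(n, dtype=object)
    n_excl = int(round(config.excluded_specialty_share * n))
    excl_idx = rng.choice(n, size=n_excl, replace=False) if n_excl else np.array([], int)
    excl_pool = np.asarray(sorted(DEFAULT_EXCLUDED_SPECIALTIES), dtype=object)
    specialty[excl_idx] = excl_pool[rng.integers(0, len(excl_pool), size=n_excl)]
    incl_mask = np.ones(n, dtype=bool)
    incl_mask[excl_idx] = False
    names = np.asarray(list(config.specialty_distribution.keys()), dtype=object)
    probs = np.asarray(list(config.specialty_distribution.values()), dtype=float)
    probs = probs / probs.sum()
    specialty[incl_mask] = rng.choice(names, size=int(incl_mask.sum()), p=probs)

    # practices are nested inside planted communities (never span them)
    practice = np.empty(n, dtype=object)
    counter = 0
    for c, s in enumerate(sizes):
        n_prac = max(1, int(round(config.n_practices * s / n)))
        n_prac = min(n_prac, s)
        members = np.flatnonzero(community == c)
        members = rng.permutation(members)
        for chunk in np.array_split(members, n_prac):
            practice[chunk] = f"PR{counter:05d}"
            counter += 1

    df = pd.DataFrame({
        "physician_id": ids,
        "specialty_code": specialty,
        "practice_id": practice,
        "region_code": config.region_code,
    })
    return df, community


def _generate_patients(rng, config, sizes):
    n = config.n_patients
    ids = np.array([f"Q{i:06d}" for i in range(n)], dtype=object)
    home = rng.choice(len(sizes), size=n, p=sizes / sizes.sum())
    age = np.clip(np.rint(rng.normal(config.mean_age, config.age_sd, size=n)),
                  1, 100).astype(int)
    gender = np.where(rng.random(n) < config.female_share, "female", "male")
    cohort = rng.random(n) >= config.noncohort_share
    dialysis = rng.random(n) < config.dialysis_share
    df = pd.DataFrame({
        "patient_id": ids,
        "birth_year": config.observation_year - age,
        "gender": gender,
    })
    return df, home, cohort, dialysis


def _generate_diagnoses(rng, config, patient_ids, cohort):
    """Qualifying records for cohort patients, safe noise for the rest."""
    weights = np.array([GROUP_PREVALENCE_PCT[g] for g in catalog.GROUP_IDS], float)
    logw = np.log(weights / weights.sum())
    rules = DEFAULT_CATALOG
    group_to_rules = {g: [i for i, r in enumerate(rules) if r.group_id == g]
                      for g in catalog.GROUP_IDS}

    coh_idx = np.flatnonzero(cohort)
    n_coh = len(coh_idx)
    rows_pid: list[np.ndarray] = []
    rows_rule: list[np.ndarray] = []

    if n_coh:
        k = np.minimum(_zero_truncated_poisson(
            rng, config.mean_diseases_per_patient, n_coh), len(catalog.GROUP_IDS))
        # Gumbel top-k == weighted sampling of distinct groups per patient
        keys = logw + rng.gumbel(size=(n_coh, len(catalog.GROUP_IDS)))
        order = np.argsort(-keys, axis=1)
        take = np.arange(len(catalog.GROUP_IDS)) < k[:, None]
        pat_rep = np.repeat(coh_idx, k)
        groups = np.asarray(catalog.GROUP_IDS)[order[take]]
        # sub-rule choice for the two split groups (1a/1b, 4a/4b)
        pick_second = rng.random(len(groups)) < 0.5
        rule_idx = np.array([
            group_to_rules[g][1] if (len(group_to_rules[g]) > 1 and p2)
            else group_to_rules[g][0]
            for g, p2 in zip(groups, pick_second)
        ])
        rows_pid.append(pat_rep)
        rows_rule.append(rule_idx)

    pid_arr = np.concatenate(rows_pid) if rows_pid else np.array([], int)
    rule_arr = np.concatenate(rows_rule) if rows_rule else np.array([], int)

    is_m2q = np.array([rules[i].frequency_rule == M2Q for i in rule_arr])
    Q = config.quarters

    out_pid: list[np.ndarray] = []
    out_rule: list[np.ndarray] = []
    out_quarter: list[np.ndarray] = []
    out_qualifier: list[np.ndarray] = []

    # M2Q: two records in two distinct quarters
    m2 = np.flatnonzero(is_m2q)
    if len(m2):
        q1 = rng.integers(0, Q, size=len(m2))
        q2 = (q1 + rng.integers(1, Q, size=len(m2))) % Q
        sp_only = np.array([rules[i].qualifier_rule == catalog.STATUS_POST_ONLY
                            for i in rule_arr[m2]])
        qual1 = np.where(sp_only | (rng.random(len(m2)) < 0.15),
                         "status_post", "confirmed")
        qual2 = np.where(sp_only | (rng.random(len(m2)) < 0.15),
                         "status_post", "confirmed")
        out_pid += [pid_arr[m2], pid_arr[m2]]
        out_rule += [rule_arr[m2], rule_arr[m2]]
        out_quarter += [q1 + 1, q2 + 1]
        out_qualifier += [qual1, qual2]

    # M1Q: one confirmed record
    m1 = np.flatnonzero(~is_m2q)
    if len(m1):
        out_pid.append(pid_arr[m1])
        out_rule.append(rule_arr[m1])
        out_quarter.append(rng.integers(0, Q, size=len(m1)) + 1)
        out_qualifier.append(np.full(len(m1), "confirmed", dtype=object))

    # non-cohort noise: exactly one record that can never satisfy any rule
    non_idx = np.flatnonzero(~cohort)
    if len(non_idx):
        kind = rng.integers(0, 3, size=len(non_idx))
        m2q_rules = [i for i, r in enumerate(rules) if r.frequency_rule == M2Q
                     and r.qualifier_rule != catalog.STATUS_POST_ONLY]
        m1q_rules = [i for i, r in enumerate(rules) if r.frequency_rule == catalog.M1Q]
        noise_rule = np.where(
            kind == 1,
            np.asarray(m2q_rules)[rng.integers(0, len(m2q_rules), len(non_idx))],
            np.asarray(m1q_rules)[rng.integers(0, len(m1q_rules), len(non_idx))],
        )
        noise_qual = np.where(kind == 1, "confirmed", "status_post")
        # kind 0 -> off-catalog code, qualifier irrelevant
        out_pid.append(non_idx)
        out_rule.append(np.where(kind == 0, -1, noise_rule))
        out_quarter.append(rng.integers(0, Q, size=len(non_idx)) + 1)
        out_qualifier.append(np.where(kind == 0, "confirmed", noise_qual))

    pid = np.concatenate(out_pid)
    rule_i = np.concatenate(out_rule)
    quarter = np.concatenate(out_quarter)
    qualifier = np.concatenate(out_qualifier)

    codes = np.empty(len(pid), dtype=object)
    in_cat = rule_i >= 0
    codes[in_cat] = _sample_icd_codes(rng, rule_i[in_cat], rules)
    n_off = int((~in_cat).sum())
    if n_off:
        pool = np.asarray(_NON_CATALOG_CODES, dtype=object)
        codes[~in_cat] = pool[rng.integers(0, len(pool), size=n_off)]

    return pd.DataFrame({
        "patient_id": patient_ids[pid],
        "icd10_code": codes,
        "quarter": quarter.astype(int),
        "qualifier": qualifier,
    })


def _generate_consultations(rng, config, patient_ids, home, dialysis,
                            physician_ids, sizes):
    n = config.n_patients
    k = len(sizes)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])

    r = config.visit_dispersion
    p = r / (r + config.mean_visits)
    n_visits = np.maximum(1, rng.negative_binomial(r, p, size=n))

    pat = np.repeat(np.arange(n), n_visits)
    V = len(pat)
    visit_home = home[pat]
    within = rng.random(V) < config.within_community_visit_prob
    if k > 1:
        offset = rng.integers(1, k, size=V)
    else:
        offset = np.zeros(V, dtype=int)
    comm = np.where(within, visit_home, (visit_home + offset) % k)
    # uniform physician inside the chosen community (communities are
    # contiguous id blocks)
    u = rng.random(V)
    phys = starts[comm] + np.floor(u * sizes[comm]).astype(int)

    window_start = np.datetime64(f"{config.observation_year}-01-01")
    month_end = config.quarters * 3
    if month_end == 12:
        window_end = np.datetime64(f"{config.observation_year + 1}-01-01")
    else:
        window_end = np.datetime64(
            f"{config.observation_year}-{month_end + 1:02d}-01")
    n_days = int((window_end - window_start) / np.timedelta64(1, "D"))
    dates = window_start + rng.integers(0, n_days, size=V).astype("timedelta64[D]")

    excluded = rng.random(V) < config.excluded_billing_share
    pool = np.asarray(_EXCLUDED_BILLING_SAMPLE, dtype=object)
    billing = np.where(excluded,
                       pool[rng.integers(0, len(pool), size=V)],
                       _INCLUDED_BILLING)

    df = pd.DataFrame({
        "patient_id": patient_ids[pat],
        "physician_id": physician_ids[phys],
        "service_date": np.datetime_as_string(dates, unit="D"),
        "billing_type_code": billing,
    })

    # dialysis patients: extra dialysis-billed contacts on top of normal care
    dial_idx = np.flatnonzero(dialysis)
    if len(dial_idx):
        n_dial = 4
        dpat = np.repeat(dial_idx, n_dial)
        dhome = home[dpat]
        dwithin = rng.random(len(dpat)) < config.within_community_visit_prob
        doffset = (rng.integers(1, k, size=len(dpat)) if k > 1
                   else np.zeros(len(dpat), dtype=int))
        dcomm = np.where(dwithin, dhome, (dhome + doffset) % k)
        du = rng.random(len(dpat))
        dphys = starts[dcomm] + np.floor(du * sizes[dcomm]).astype(int)
        ddates = window_start + rng.integers(0, n_days, size=len(dpat)
                                             ).astype("timedelta64[D]")
        extra = pd.DataFrame({
            "patient_id": patient_ids[dpat],
            "physician_id": physician_ids[dphys],
            "service_date": np.datetime_as_string(ddates, unit="D"),
            "billing_type_code": _DIALYSIS_BILLING,
        })
        df = pd.concat([df, extra], ignore_index=True)
    return df


def generate_bundle(config: SimConfig) -> tuple[ClaimsBundle, GroundTruth]:
    """Generate the four claims tables plus their planted ground truth."""
    rng = np.random.default_rng(config.seed)
    sizes = _community_sizes(config)

    physicians, phys_comm = _generate_physicians(rng, config, sizes)
    patients, home, cohort, dialysis = _generate_patients(rng, config, sizes)

    diagnoses = _generate_diagnoses(
        rng, config, patients["patient_id"].to_numpy(), cohort)
    consultations = _generate_consultations(
        rng, config, patients["patient_id"].to_numpy(), home, dialysis,
        physicians["physician_id"].to_numpy(), sizes)

    bundle = ClaimsBundle(physicians=physicians, patients=patients,
                          consultations=consultations, diagnoses=diagnoses)
    truth = GroundTruth(
        physician_community=dict(zip(physicians["physician_id"],
                                     phys_comm.tolist())),
        patient_home_community=dict(zip(patients["patient_id"], home.tolist())),
        cohort_flag=dict(zip(patients["patient_id"], cohort.tolist())),
        dialysis_flag=dict(zip(patients["patient_id"], dialysis.tolist())),
    )
    return bundle, truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    path = Path(path)
    write_table(
        pd.DataFrame(sorted(truth.physician_community.items()),
                     columns=["physician_id", "planted_community"]),
        path / "ground_truth_physicians.csv")
    pat = pd.DataFrame(sorted(truth.patient_home_community.items()),
                       columns=["patient_id", "home_community"])
    pat["cohort_flag"] = pat["patient_id"].map(truth.cohort_flag)
    pat["dialysis_flag"] = pat["patient_id"].map(truth.dialysis_flag)
    write_table(pat, path / "ground_truth_patients.csv")


def simulate_to_dir(config: SimConfig, out: str | Path) -> None:
    """Generate a bundle and write it (plus ground truth) to ``out``."""
    bundle, truth = generate_bundle(config)
    write_bundle(bundle, out)
    write_ground_truth(truth, out)
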