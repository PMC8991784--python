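# Methods

This note documents the models, rules and numerical choices behind
`physnet`, and what the synthetic data do and do not establish.

## Cohort rules

The patient cohort is defined by 14 ambulatory care-sensitive diagnosis
groups coded in ICD-10 (`physnet.catalog`). Two frequency rules validate a
diagnosis against coding noise: **M2Q** (chronic conditions) requires
records in at least two *distinct* quarters of the one-year observation
window; **M1Q** (acute conditions: bronchitis, gastroenteritis, intestinal
infections, influenza/pneumonia, ENT infections) requires one record.
Qualifier rules restrict the diagnosis-certainty labels that count:
M1Q groups accept only "confirmed"; most M2Q groups accept "confirmed" or
"status post"; the ischemic-heart-disease sub-rule for I21–I24 accepts
only "status post". The two qualifying quarters of an M2Q group may carry
different qualifiers — the rules impose no same-qualifier constraint.
Sub-rules 1a/1b and 4a/4b are evaluated separately but reported under
their merged group, so group counts have 14 levels.

ICD matching is by string prefix at the printed precision of the catalog:
`I10` matches `I10`, `I10.0`, `I10.90`; `R07.0` matches only
`R07.0`-prefixed codes; ranges such as `I10–I15` expand to the inclusive
list of three-character codes. Codes are never truncated before matching.

Dialysis patients are identified by a configurable billing-code set
(`dialysis_billing_types`, default `{"dialysis"}`) because claims data
carry no dialysis flag; any such patient is excluded entirely. An
adults-only restriction is a configurable minimum age (default 18) applied
at the observation year. The face-to-face consultation filter is a fully
configurable billing-code exclusion list, since billing catalogs differ
between settings.

## Sharing graph

Edge weight = distinct cohort patients with at least one qualifying
consultation with both physicians, enumerated per patient over C(k, 2)
physician pairs (provably identical to pairwise panel intersection, and
scalable). Panel size = distinct cohort patients of a physician; the
relative threshold is inclusive (≥ 5%) and must hold for at least one of
the two panels. Defaults: 20 shared patients, 5%, both configurable.
Physicians losing all edges remain as flagged isolates — they stay outside
every network but their treatment days still count in allocation
denominators.

## Community detection

Modularity is the standard weighted Newman–Girvan quality at resolution 1.
The multilevel (Louvain) optimizer is implemented in-package to guarantee
reproducibility properties that library implementations do not expose:

* vertex visiting order is a seeded shuffle, renewed each local-moving
  pass;
* among equal-gain target communities the lowest community label wins
  (gain ties resolved at 1e-12 absolute tolerance);
* aggregated levels carry self-loop weights; community labels are
  canonicalized by each community's smallest vertex id.

Identical graph + seed therefore yields an identical partition. Tests
check the result against exhaustive enumeration of all set partitions on
small graphs (the greedy optimum never exceeds the global one and attains
it on clique-pair fixtures) and the Q formula against networkx.

The size band [20, 120] is enforced iteratively: any community above the
maximum is re-partitioned on its induced subgraph with original weights
(no re-thresholding). A subgraph the algorithm returns as a single
community is terminal; it is retained and flagged even if oversized,
because forcing a k-way cut would manufacture structure the data do not
support. Undersized communities (< 20) are discarded once, after the whole
recursion finishes, so that small fragments of an oversized community are
not lost before that community's own recursion completes. An edgeless
(sub)graph yields singleton communities with a warning, since modularity
is undefined at zero total weight.

## Allocation

Treatment days are distinct (physician, date) units by default: two
physicians seen on the same date count as two days. A `calendar_day`
variant (distinct dates) is available via `day_granularity`. The majority
rule is strict (> 50%), so at most one network can win and no tie-breaking
is needed; the denominator includes days with discarded/isolated
physicians, but never billing-excluded contacts. An independent
recount-based audit (`audit_allocation`) re-derives every allocated
patient's share from raw consultations and runs by default in
`run_pipeline`.

## Network statistics

Degree centrality is the network-level ratio E/V; density and transitivity
(3 × triangles / connected triples) are computed on the unweighted
intra-network subgraph — weighted variants are out of scope. Central
physicians are ranked by intra-network degree with ties broken by id.
Within-network proportions are patient-averaged (the pooled variant can be
derived from the allocation table). Spearman correlations use average
ranks for ties, t-distribution p-values, pairwise deletion, and are
flagged at the 0.1% significance level; constant columns yield missing
values rather than an arbitrary sign.

## Synthetic claims generator

The generator (`physnet.simulate`) emulates a one-year regional claims
extract with planted ground truth. Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| n_physicians / n_planted_communities | 120 / 4 | four communities of 30, inside the 20–120 band after filtering |
| specialty_distribution | 45% GP, 10% gynecology, 5% orthopedics/ophthalmology, ... | typical composition of ambulatory physician networks |
| excluded_specialty_share | 8% | gives the specialty filter real work |
| n_patients | 4000 | ~33 patients/physician, enough for within-community pairs to clear the 20-shared-patient threshold |
| mean_diseases_per_patient | 2.5 (zero-truncated Poisson) | multimorbid ACSC population |
| mean_age / female_share | 54 years / 55% | ACSC cohort demographics |
| mean_visits / dispersion | 10 per patient-year, NB dispersion 2 | ambulatory contact rates are overdispersed; visit-rate distributions are not published for the target data, so this is a free parameter |
| within_community_visit_prob | 0.9 | strong but imperfect loyalty, leaves cross-community noise edges |
| noncohort_share | 30% | patients that must be rejected by the diagnosis rules |
| excluded_billing_share / dialysis_share | 5% / 1% | exercise the consultation and dialysis filters |

Mechanics: physicians are split into planted communities (optionally with
explicit `community_sizes`); practices are nested inside communities;
patients draw a home community proportional to community size; each
consultation targets the home community with probability
`within_community_visit_prob`, else a uniformly random other community.
Cohort patients receive qualifying diagnosis records by construction
(M2Q groups in two distinct quarters, sampling groups without replacement
with weights proportional to observed large-population prevalences);
non-cohort patients receive exactly one record that can never qualify
(off-catalog code, single-quarter M2Q code, or an M1Q code with a
rejected qualifier). Roughly 30% of catalog codes get a random fourth
digit so prefix matching is exercised. All randomness flows through one
`numpy` generator, so a fixed seed reproduces the bundle byte-for-byte.

What the generator does **not** emulate: real billing-code dictionaries,
geographic structure, seasonality, physician-specific visit propensities,
practices spanning communities, or patients moving between regions.
Passing recovery tests on these data therefore show that the pipeline
correctly recovers community structure *of the planted kind*; they do not
certify performance on real claims, where community structure is weaker
and overlapping.

## Problem sizes in tests and the acceptance script

The shipped checks use a default-scale run (120 physicians, 4000
patients, ten seeds for recovery) and one heterogeneous run with 200
planted networks of 25–55 physicians (~8,100 physicians, ~285,000
patients, ~2.4 million consultation rows) for the correlation-sign
analysis. These sizes give stable statistics while keeping a full run in
the minutes range on a single CPU; the qualitative results (perfect
planted recovery, positive size–patients and negative size–density rank
correlations) are insensitive to moderate scale changes.

## Known limitations

* The Louvain implementation is pure Python; graphs beyond ~10^5 edges
  will be noticeably slower than igraph's C implementation (identical
  objective, different tie-breaking).
* Edge definitions are year-aggregated; time-windowed co-visit edges are
  out of scope.
* Regions are processed as given; the package does not merge or map
  regional associations.
* With `calendar_day` granularity a date shared across networks counts
  once per network, so per-network day counts can exceed the total; the
  default `physician_day` granularity avoids this.
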