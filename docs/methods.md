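# Methods

`followkit` turns routine oncological follow-up documentation into survival
analyses. This note records the statistical model, the conventions the
implementation fixes where the underlying documentation practice is silent,
what the synthetic cohort generator does and does not emulate, and the known
limitations.

## Data model

One generic follow-up form covers the survival-relevant core shared by the
two pilot departments (urology / prostate cancer, haematology / AML):
patient identity, initial diagnosis (date, text, classification), initial
therapy (date, text, classification), study participation, and the
follow-up contact (date, status, information source, entry mode). A patient
accumulates one form per follow-up visit. Department specifics are confined
to vocabularies: each department has its own status list and study list.

Status labels map unambiguously to two binary endpoints:

* **OS flag** — the status denotes death from any cause;
* **EFS flag** — the status denotes relapse/progression or death.

Structurally every death is also an EFS event, so `os_flag = 1` implies
`efs_flag = 1`; `StatusMapping` enforces this at construction. The shipped
default vocabularies are the two departments' published status lists.

Documents are exchanged in a fixed subset of CDISC ODM 1.3.1: a `Study`
whose metadata defines the form as five item groups plus per-department
code lists (status code-list items carry the OS/EFS flags as `Alias`
elements), and a `ClinicalData` block with one `FormData` per
documentation event. Concept annotation codes (e.g. SNOMED CT) are carried
as opaque `Alias` values and round-tripped, never interpreted or
validated. Serialization is deterministic (stable ordering, no implicit
timestamps) so identical documents are byte-identical — a property the
reproducibility tests rely on.

## Imprecise dates

Follow-up documentation often knows a date only to the month or year
("Oct. 2008", "2007"). Dates are therefore stored with an explicit
precision (day / month / year), serialized as ISO 8601 truncated forms
(`YYYY-MM-DD`, `YYYY-MM`, `YYYY`), and resolved for analysis by the
**midpoint convention**: month → the 15th, year → July 1. Midpoint
resolution minimises the maximum resolution error, is symmetric, and keeps
resolution deterministic and order-preserving for non-overlapping ranges.
Interval-censoring likelihoods are deliberately out of scope; the midpoint
convention is the only way imprecise dates enter the analysis, and a
month-precision date can therefore shift an event by up to ±15 days and a
year-precision date by up to ±6 months.

## From forms to survival records

* **Deduplication.** The current status is always taken from the most
  current form: latest resolved follow-up date, ties broken by entry
  timestamp, then by form id (a total order, so deduplication is
  idempotent and independent of input order). Forms without a follow-up
  date can never be "current".
* **Origin.** Observation time starts at the earliest documented therapy
  start date across the patient's forms (default), or the earliest
  diagnosis date when requested.
* **OS.** Time runs from origin to the current follow-up contact;
  the event indicator is the OS flag of the current status.
* **EFS.** Time runs from origin to the *earliest* form whose status is
  EFS-positive — event-free survival measures time to first event, and
  relapses are recorded on interim forms — or to the current contact with
  no event. A death without a separately documented death date uses the
  form's follow-up date as the event date, since the form carries exactly
  one date (the last contact with its status).
* **Durations** are day counts divided by 365.25.
* **Exclusions.** Patients without an origin date, without a dated and
  labelled current form, or with a follow-up before the origin (a likely
  data error) are excluded with an explicit reason. Exclusions feed the
  data-quality report and the pipeline log; they are never silent, and
  parsed = analyzed + excluded always holds.

## Survival estimation

The Kaplan-Meier product-limit estimator and its companions are computed
from first principles (no survival library stands behind them):

* S(t) = prod over event times t_i <= t of (1 − d_i/n_i); at tied times,
  events are processed before censorings (subjects censored at t remain in
  the risk set for events at t) — the standard product-limit convention.
* Greenwood's variance: Var[S(t)] = S(t)^2 · sum d_i / (n_i (n_i − d_i)).
  The sum diverges if the last subject dies (S = 0); the curve is reported
  with a degenerate [0, 0] interval there.
* Confidence intervals default to the **log transform** — a symmetric
  normal interval on log S, clipped to [0, 1] — matching the default of
  the R `survival` implementation this package was cross-checked against.
  `plain` and `log-log` (exponential Greenwood, the lifelines default) are
  available via `ci_transform`; the test suite verifies exact agreement
  with both references.
* Median survival: the smallest observed time with S(t) ≤ 0.5, reported
  as "not reached" (`None`) when the curve never gets there. At an exact
  S = 0.5 plateau the plateau's first time is returned.
* `survival_at` evaluates the right-continuous step function; numbers at
  risk at time t count records with observation time ≥ t.
* Log-rank test: at each distinct event time, expected events per group
  follow the hypergeometric model e_gj = n_gj d_j / n_j with the
  multivariate hypergeometric covariance; the statistic is the quadratic
  form of (O − E) over the first g − 1 groups using a Moore-Penrose
  generalized inverse for numerical safety, referred to chi-square with
  g − 1 degrees of freedom. No continuity correction is applied. Times
  with a single subject at risk contribute no variance.

## Completeness reporting

Computed on patient-level current forms (one case per patient; the
published table's "cases" wording is ambiguous between forms and patients,
and the patient reading matches its stratum totals):

* **Item completeness**: availability of therapy start date, follow-up
  status and follow-up date — the three items the survival analysis needs —
  per entry-mode stratum (routine / retrospective / total), plus joint
  all-three availability. Percentages are rounded half-up to one decimal
  using exact decimal arithmetic.
* **Form completeness**: the fraction of an eligible population with at
  least one form carrying survival information (follow-up date and
  status).
* **Clark's C**: total observed person-time over total potential
  person-time, the potential ending at death (death closes follow-up) or
  at the study end. A last contact beyond the study end clamps that
  patient's potential to the observed time, with a warning.

`fixture_from_counts` reconstructs documents with exact per-item missing
counts: the n − all_three incomplete patients are covered by sequential
block assignment with wrap-around, which is deterministic, satisfies any
feasible `max(missing) ≤ n − all_three ≤ sum(missing)` configuration, and
places double-missingness on the lexicographically first patients.

## Synthetic cohort generator

`simulate_cohort` emulates the documented two-department cohort: accrual
uniform over 1992-06-03 … 2008-12-31, administrative censoring at
2010-05-31, ~21% routine entry (207/965), per-item missingness at the
published rates (23/965, 15/965, 55/965), a mean of 1029/965 forms per
patient, and independent exponential relapse and death times with defaults
ln 2 / 16.4 y⁻¹ (death) and ln 2 / 7.7 − ln 2 / 16.4 y⁻¹ (relapse), so the
latent median OS is 16.4 years and the latent median time to first event
7.7 years. Follow-up visits are annual from therapy start; a form's status
is drawn from the department vocabulary consistently with the latent
history (relapse statuses never precede the latent relapse, death only on
the final form). The imprecise-date rate (default 5%) degrades dates to
month or year precision; no published rate exists, so the default is a
plausible registry-scale choice.

What the generator does **not** emulate, hence what a green test does not
establish:

* Visit discretisation right-shifts *observed* EFS: with sparse interim
  forms a relapse is often first documented on the final form, so the
  pipeline's EFS median exceeds the latent 7.7 y. OS is unaffected (death
  dates are exact), which is why exponential-recovery acceptance runs on
  OS.
* Alive patients are censored exactly at the study end, so Clark's C on a
  default synthetic cohort is ≈ 1 by construction — unlike the real-world
  value, which reflects patients lost to follow-up. Loss to follow-up is
  not modelled.
* No PSA kinetics, remission dynamics, non-annual visit schedules, or
  department-specific hazards.

## Numerical and design choices

* Exact decimal half-up rounding for printed percentages (binary-float
  rounding would mis-round e.g. 88.45).
* CSV exports serialize durations with `repr` (shortest round-tripping
  form) so re-imported records are bit-identical; rows are ordered by
  pseudonym for determinism.
* Pseudonyms are treated as already opaque; an optional keyed-hash pass
  (HMAC-SHA256, truncated) re-pseudonymizes CSV exports without a lookup
  table.
* When a parsed document carries no entry timestamps, document order
  supplies the deduplication tie-break key.
* The Monte-Carlo acceptance checks are sized to the property being
  measured: the log-rank null calibration uses 1000 two-group simulations
  (50 subjects per group) and the p-uniformity check 2000; the exponential
  median-recovery check through the full pipeline averages four seeded
  5000-patient cohorts because a single cohort under the accrual-window
  censoring estimates the median with ~4% Monte-Carlo scatter.

## Known limitations

* Exact-match vocabularies only; no fuzzy status matching.
* The ODM dialect is a fixed subset; arbitrary ODM documents are rejected.
* Completeness metrics measure presence, not accuracy, of items.
* The published cohort's clinical statistics (median OS 16.4 y, EFS 7.7 y,
  Table of 5-/10-year probabilities, grouped p-values) depend on the
  unpublished patient-level dataset and are not reproducible here; the
  survival engine is instead validated against mathematical ground truth
  and independent reference implementations.
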