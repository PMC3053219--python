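"""Synthetic follow-up cohorts with known ground truth.

The generator emulates a two-department oncology cohort (prostate cancer
in urology, AML in haematology) documented on the generic follow-up form:
patients accrue uniformly over an accrual window, relapse and death times
are independent exponentials, observation is administratively censored at
the study end, and one form is written per follow-up visit (annual
schedule) with the status drawn from the department vocabulary
consistently with the latent event history.  Item-level missingness,
imprecise dates and routine-vs-retrospective entry are injected at
configurable rates.

Defaults mirror the published cohort: 965 patients, follow-up window
1992-06-03 to 2010-05-31, ~21% routine entry (207/965), item missingness
matching the published completeness table (therapy date 23/965, status
15/965, follow-up date 55/965), and hazards chosen so the median overall
survival is 16.4 years and the median event-free survival 7.7 years
(``ln 2 / median``).

``fixture_from_counts`` builds small deterministic documents that
reproduce exact per-item missing counts, for reconstructing published
completeness tables.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np

from .dates import ImpreciseDate
from .model import (
    DEFAULT_MAPPINGS,
    DEFAULT_STUDY_LISTS,
    FollowUpForm,
    FormDocument,
    ValidationError,
)

#: ln 2 / 16.4 y — exponential death hazard giving the published median OS.
DEFAULT_HAZARD_DEATH = math.log(2) / 16.4
#: Relapse hazard such that the combined event hazard gives median EFS 7.7 y.
DEFAULT_HAZARD_RELAPSE = math.log(2) / 7.7 - math.log(2) / 16.4

_DEATH_STATUSES = {
    "urology": (
        "Death of prostate cancer",
        "Death independent from prostate cancer",
        "Death of unknown cause",
    ),
    "haematology": (
        "Death of AML",
        "Death independent from AML",
        "Death of unknown cause",
    ),
}
_RELAPSE_STATUSES = {
    "urology": ("Relapse (PSA)", "Relapse (imaging)"),
    "haematology": ("Relapse", "Persistent AML"),
}
_EVENT_FREE_STATUSES = {
    "urology": ("Relapse free",),
    "haematology": ("First remission", "Second remission"),
}

#: Opaque concept annotation codes carried on item definitions (never
#: interpreted; present so metadata round-trips are exercised).
DEFAULT_ITEM_ANNOTATIONS = {
    "diagnosis_date": "432213005",
    "therapy_date": "413350009",
    "followup_date": "410671006",
    "status_label": "263490005",
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated follow-up cohort."""

    n_patients: int = 965
    department_mix: dict = field(
        default_factory=lambda: {"urology": 0.9, "haematology": 0.1}
    )
    hazard_death: float = DEFAULT_HAZARD_DEATH
    hazard_relapse: float = DEFAULT_HAZARD_RELAPSE
    accrual_start: dt.date = dt.date(1992, 6, 3)
    accrual_end: dt.date = dt.date(2008, 12, 31)
    study_end: dt.date = dt.date(2010, 5, 31)
    routine_fraction: float = 207 / 965
    missing_therapy_date: float = 23 / 965
    missing_status: float = 15 / 965
    missing_followup_date: float = 55 / 965
    imprecise_date_rate: float = 0.05
    forms_per_patient_mean: float = 1029 / 965
    study_enrollment_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValidationError("n_patients must be positive")
        if abs(sum(self.department_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("department mix fractions must sum to 1")
        if any(d not in DEFAULT_MAPPINGS for d in self.department_mix):
            raise ValidationError(
                f"unknown department in mix: {sorted(self.department_mix)}"
            )
        if self.hazard_death < 0 or self.hazard_relapse < 0:
            raise ValidationError("hazards must be non-negative")
        if not self.accrual_start < self.accrual_end < self.study_end:
            raise ValidationError(
                "need accrual_start < accrual_end < study_end"
            )
        for name in (
            "routine_fraction",
            "missing_therapy_date",
            "missing_status",
            "missing_followup_date",
            "imprecise_date_rate",
            "study_enrollment_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        if self.forms_per_patient_mean < 1.0:
            raise ValidationError("forms_per_patient_mean must be >= 1")


def _degrade(date: dt.date, rng: np.random.Generator, rate: float) -> ImpreciseDate:
    """Randomly truncate a date to month or year precision."""
    if rate > 0 and rng.random() < rate:
        if rng.random() < 2 / 3:
            return ImpreciseDate(date.year, date.month)
        return ImpreciseDate(date.year)
    return ImpreciseDate.from_date(date)


def simulate_cohort(spec: CohortSpec) -> FormDocument:
    """Simulate a follow-up document; identical spec + seed → identical cohort."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    departments = sorted(spec.department_mix)
    mix = np.array([spec.department_mix[d] for d in departments])
    accrual_days = (spec.accrual_end - spec.accrual_start).days

    doc = FormDocument(
        code_lists=dict(DEFAULT_MAPPINGS),
        study_lists=dict(DEFAULT_STUDY_LISTS),
        metadata={"file_oid": f"followkit.sim.{spec.seed}"},
        item_annotations=dict(DEFAULT_ITEM_ANNOTATIONS),
    )
    width = max(4, len(str(spec.n_patients)))
    timestamp = 0
    for i in range(spec.n_patients):
        pid = f"P{i + 1:0{width}d}"
        department = departments[int(rng.choice(len(departments), p=mix))]
        therapy = spec.accrual_start + dt.timedelta(
            days=int(rng.integers(0, accrual_days + 1))
        )
        diagnosis = therapy - dt.timedelta(days=int(rng.integers(14, 91)))
        max_years = (spec.study_end - therapy).days / 365.25

        t_death = (
            rng.exponential(1.0 / spec.hazard_death)
            if spec.hazard_death > 0
            else math.inf
        )
        t_relapse = (
            rng.exponential(1.0 / spec.hazard_relapse)
            if spec.hazard_relapse > 0
            else math.inf
        )
        died = t_death <= max_years
        if died:
            last_contact = therapy + dt.timedelta(days=round(t_death * 365.25))
        else:
            last_contact = spec.study_end
        relapsed_by = lambda d: t_relapse <= (d - therapy).days / 365.25

        # Annual visit dates strictly before the final contact.
        visits = []
        k = 1
        while True:
            visit = therapy + dt.timedelta(days=round(k * 365.25))
            if visit >= last_contact:
                break
            visits.append(visit)
            k += 1
        n_interim = min(
            len(visits), int(rng.poisson(spec.forms_per_patient_mean - 1.0))
        )
        if n_interim > 0:
            chosen = sorted(
                rng.choice(len(visits), size=n_interim, replace=False)
            )
            interim_dates = [visits[j] for j in chosen]
        else:
            interim_dates = []

        entry_mode = (
            "routine" if rng.random() < spec.routine_fraction else "retrospective"
        )
        miss_therapy = rng.random() < spec.missing_therapy_date
        miss_status = rng.random() < spec.missing_status
        miss_followup = rng.random() < spec.missing_followup_date
        study = None
        if rng.random() < spec.study_enrollment_rate:
            options = DEFAULT_STUDY_LISTS[department]
            study = options[int(rng.integers(0, len(options)))]
        source = None
        if died and rng.random() < 0.3:
            source = "registration office"
        elif rng.random() < 0.1:
            source = "general practitioner"

        contact_dates = interim_dates + [last_contact]
        for j, contact in enumerate(contact_dates):
            final = j == len(contact_dates) - 1
            if final and died:
                weights = np.array([0.6, 0.3, 0.1])
                status = _DEATH_STATUSES[department][
                    int(rng.choice(3, p=weights))
                ]
            elif relapsed_by(contact):
                options = _RELAPSE_STATUSES[department]
                status = options[int(rng.integers(0, len(options)))]
            else:
                options = _EVENT_FREE_STATUSES[department]
                status = options[int(rng.integers(0, len(options)))]
            doc.forms.append(
                FollowUpForm(
                    patient_pseudonym=pid,
                    department=department,
                    form_id=f"{pid}.{j + 1}",
                    diagnosis_date=_degrade(
                        diagnosis, rng, spec.imprecise_date_rate
                    ),
                    diagnosis_text=(
                        "prostate cancer"
                        if department == "urology"
                        else "acute myeloid leukaemia"
                    ),
                    diagnosis_classification=(
                        "C61" if department == "urology" else "C92.0"
                    ),
                    therapy_date=(
                        None
                        if miss_therapy
                        else _degrade(therapy, rng, spec.imprecise_date_rate)
                    ),
                    therapy_text=(
                        "radical prostatectomy"
                        if department == "urology"
                        else "induction chemotherapy"
                    ),
                    therapy_classification=None,
                    study=study,
                    followup_date=(
                        None
                        if (final and miss_followup)
                        else _degrade(contact, rng, spec.imprecise_date_rate)
                    ),
                    status_label=None if (final and miss_status) else status,
                    source=source if final else None,
                    entry_mode=entry_mode,
                    entry_timestamp=timestamp,
                )
            )
            timestamp += 1
    return doc


def fixture_from_counts(
    n: int,
    missing_per_item: tuple[int, int, int],
    all_three_present: int,
    entry_mode: str = "routine",
    department: str = "urology",
    patient_prefix: str = "P",
) -> FormDocument:
    """Deterministic document reproducing exact per-item missing counts.

    ``missing_per_item`` gives missing counts for (therapy start date,
    follow-up status, follow-up date).  Exactly ``all_three_present``
    patients carry all three items.  Feasibility requires
    ``max(missing_i) <= n - all_three_present <= sum(missing_i)``; the
    overlap of missing sets is constructed greedily (sequential blocks
    with wrap-around), so double-missingness lands on the
    lexicographically first patients.  Deterministic, independent of any
    seed.
    """
    m_therapy, m_status, m_followup = missing_per_item
    if min(missing_per_item) < 0 or all_three_present < 0 or n <= 0:
        raise ValueError("counts must be non-negative and n positive")
    u = n - all_three_present
    if u < 0:
        raise ValueError(f"all_three_present={all_three_present} exceeds n={n}")
    if max(missing_per_item) > u:
        raise ValueError(
            f"infeasible: max(missing)={max(missing_per_item)} > "
            f"n - all_three_present = {u}"
        )
    if sum(missing_per_item) < u:
        raise ValueError(
            f"infeasible: sum(missing)={sum(missing_per_item)} < "
            f"n - all_three_present = {u}"
        )

    # Sequential block assignment with wrap-around over the u incomplete
    # patients: covers all of them, and the sum-u surplus assignments wrap
    # back onto the first patients.
    missing_sets: list[set[int]] = [set(), set(), set()]
    pos = 0
    for item_idx, m in enumerate(missing_per_item):
        for j in range(m):
            missing_sets[item_idx].add((pos + j) % u if u else 0)
        pos += m

    width = max(4, len(str(n)))
    doc = FormDocument(
        code_lists=dict(DEFAULT_MAPPINGS),
        study_lists=dict(DEFAULT_STUDY_LISTS),
        metadata={"file_oid": f"followkit.fixture.{n}"},
    )
    status = (
        "Relapse free" if department == "urology" else "First remission"
    )
    for i in range(n):
        pid = f"{patient_prefix}{i + 1:0{width}d}"
        incomplete = i < u
        doc.forms.append(
            FollowUpForm(
                patient_pseudonym=pid,
                department=department,
                form_id=f"{pid}.1",
                diagnosis_date=ImpreciseDate(1999, 12, 1),
                therapy_date=(
                    None
                    if incomplete and i in missing_sets[0]
                    else ImpreciseDate(2000, 1, 1)
                ),
                status_label=(
                    None if incomplete and i in missing_sets[1] else status
                ),
                followup_date=(
                    None
                    if incomplete and i in missing_sets[2]
                    else ImpreciseDate(2005, 6, 15)
                ),
                entry_mode=entry_mode,
                entry_timestamp=i,
            )
        )
    return doc
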