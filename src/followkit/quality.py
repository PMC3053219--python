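"""Completeness reporting for follow-up documentation.

Three complementary views of data quality, all on patient-level current
forms (one case per patient):

* **item completeness** — per entry mode (routine vs retrospective) and in
  total, the fraction of cases carrying each of the three items mandatory
  for survival analysis (therapy start date, follow-up status, follow-up
  date), plus the fraction with all three;
* **form completeness** — the fraction of an eligible patient population
  having at least one follow-up form with survival information (a
  follow-up date and a status);
* **Clark's completeness C** — total observed person-time of follow-up as
  a fraction of the total potential person-time, where a patient's
  potential follow-up ends at death (death closes follow-up) or otherwise
  at the study end date.

Percentages are rounded half-up to one decimal.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .harmonize import SurvivalRecord, deduplicate
from .model import FollowUpForm

SURVIVAL_ITEMS = ("therapy_start_date", "followup_status", "followup_date")

_ITEM_ATTR = {
    "therapy_start_date": "therapy_date",
    "followup_status": "status_label",
    "followup_date": "followup_date",
}


def percentage(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to 1 decimal; exact decimal arithmetic."""
    if denominator == 0:
        return 0.0
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ItemStratum:
    """Item availability within one entry-mode stratum."""

    stratum: str
    case_count: int
    available: dict[str, int]
    all_three_count: int

    def item_percentage(self, item: str) -> float:
        return percentage(self.available[item], self.case_count)

    @property
    def all_three_percentage(self) -> float:
        return percentage(self.all_three_count, self.case_count)


@dataclass
class CompletenessReport:
    """Item-, form- and person-time-level completeness statistics."""

    strata: dict[str, ItemStratum] = field(default_factory=dict)
    form_completeness: tuple[int, int, float] | None = None
    clark_c: float | None = None

    def to_rows(self) -> list[dict]:
        """Flatten to rows (stratum, item, available, total, percentage)."""
        rows = []
        for name in ("routine", "retrospective", "total"):
            s = self.strata.get(name)
            if s is None:
                continue
            for item in SURVIVAL_ITEMS:
                rows.append(
                    {
                        "stratum": name,
                        "item": item,
                        "available": s.available[item],
                        "total": s.case_count,
                        "percentage": s.item_percentage(item),
                    }
                )
            rows.append(
                {
                    "stratum": name,
                    "item": "all_three",
                    "available": s.all_three_count,
                    "total": s.case_count,
                    "percentage": s.all_three_percentage,
                }
            )
        if self.form_completeness is not None:
            with_form, eligible, pct = self.form_completeness
            rows.append(
                {
                    "stratum": "eligible",
                    "item": "has_followup_form",
                    "available": with_form,
                    "total": eligible,
                    "percentage": pct,
                }
            )
        if self.clark_c is not None:
            rows.append(
                {
                    "stratum": "person_time",
                    "item": "clark_c",
                    "available": "",
                    "total": "",
                    "percentage": percentage(
                        round(self.clark_c * 1_000_000), 1_000_000
                    ),
                }
            )
        return rows

    def to_csv(self) -> str:
        import csv as _csv
        import io

        buf = io.StringIO()
        writer = _csv.DictWriter(
            buf,
            fieldnames=["stratum", "item", "available", "total", "percentage"],
            lineterminator="\n",
        )
        writer.writeheader()
        writer.writerows(self.to_rows())
        return buf.getvalue()


def _stratum_from_forms(name: str, forms: list[FollowUpForm]) -> ItemStratum:
    available = {item: 0 for item in SURVIVAL_ITEMS}
    all_three = 0
    for form in forms:
        present = {
            item: getattr(form, attr) is not None
            for item, attr in _ITEM_ATTR.items()
        }
        for item, ok in present.items():
            available[item] += ok
        all_three += all(present.values())
    return ItemStratum(
        stratum=name,
        case_count=len(forms),
        available=available,
        all_three_count=all_three,
    )


def item_completeness(current_forms: list[FollowUpForm]) -> CompletenessReport:
    """Item completeness per entry-mode stratum and in total.

    Input is one current form per patient (after deduplication).  An empty
    input yields an empty (zero-count) report, not an error.
    """
    routine = [f for f in current_forms if f.entry_mode == "routine"]
    retrospective = [f for f in current_forms if f.entry_mode == "retrospective"]
    report = CompletenessReport()
    report.strata["routine"] = _stratum_from_forms("routine", routine)
    report.strata["retrospective"] = _stratum_from_forms(
        "retrospective", retrospective
    )
    report.strata["total"] = _stratum_from_forms("total", current_forms)
    return report


def current_forms(forms_by_patient: dict[str, list[FollowUpForm]]) -> list[FollowUpForm]:
    """One current form per patient, ordered by pseudonym."""
    return [
        deduplicate(forms)[0]
        for _, forms in sorted(forms_by_patient.items())
    ]


def form_completeness(
    eligible_patient_ids: set[str] | list[str],
    forms: list[FollowUpForm],
) -> tuple[int, int, float]:
    """Fraction of eligible patients with >= 1 form carrying survival info.

    A form carries survival information when both a follow-up date and a
    status are present.  Forms of patients outside the eligible set are
    ignored.  Returns ``(count_with_form, eligible_count, percentage)``.
    """
    eligible = set(eligible_patient_ids)
    if not eligible:
        raise ValueError("eligible patient set must be non-empty")
    with_form = {
        f.patient_pseudonym
        for f in forms
        if f.patient_pseudonym in eligible
        and f.followup_date is not None
        and f.status_label is not None
    }
    count = len(with_form)
    return count, len(eligible), percentage(count, len(eligible))


def clark_completeness(
    records: list[SurvivalRecord], study_end: dt.date
) -> float:
    """Clark's follow-up completeness C as a fraction in [0, 1].

    ``C = sum(observed person-time) / sum(potential person-time)`` where a
    patient's observed time runs from origin to last contact and the
    potential time ends at death (for patients who died — death closes
    follow-up) or at ``study_end`` otherwise.  A last contact after
    ``study_end`` clamps that patient's potential time to the last contact,
    with a warning.
    """
    if not records:
        raise ValueError("clark_completeness requires at least one record")
    observed_total = 0.0
    potential_total = 0.0
    for r in records:
        if study_end < r.origin_date:
            raise ValueError(
                f"study_end {study_end} precedes origin of patient "
                f"{r.patient_pseudonym!r}"
            )
        observed = (r.last_contact_date - r.origin_date).days
        if r.os_event == 1:
            potential = observed
        else:
            potential = (study_end - r.origin_date).days
            if r.last_contact_date > study_end:
                warnings.warn(
                    f"patient {r.patient_pseudonym!r}: last contact after "
                    f"study end; potential time clamped to last contact",
                    stacklevel=2,
                )
                potential = observed
        observed_total += observed
        potential_total += potential
    if potential_total == 0:
        return 1.0
    return observed_total / potential_total


def full_report(
    current_patient_forms: list[FollowUpForm],
    records: list[SurvivalRecord] | None = None,
    study_end: dt.date | None = None,
    eligible_patient_ids: set[str] | None = None,
    all_forms: list[FollowUpForm] | None = None,
) -> CompletenessReport:
    """Assemble the complete data-quality report."""
    report = item_completeness(current_patient_forms)
    if eligible_patient_ids is not None:
        report.form_completeness = form_completeness(
            eligible_patient_ids, all_forms if all_forms is not None else current_patient_forms
        )
    if records is not None and study_end is not None and records:
        report.clark_c = clark_completeness(records, study_end)
    return report
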