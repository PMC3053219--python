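"""Harmonize follow-up forms into analysis-ready survival records.

A patient accumulates one form per follow-up visit; the current survival
status is always taken from the most current form (latest follow-up date,
ties broken by entry timestamp, then form id).  Observation time runs from
an origin date — the earliest documented therapy start by default, or the
earliest diagnosis date — to the current follow-up contact, in years of
365.25 days.

Two endpoints are derived from the department status vocabulary:

* overall survival (OS): event if the current status maps to death;
* event-free survival (EFS): event at the EARLIEST form whose status is
  EFS-positive (relapse or death), because event-free survival measures
  time to first event and relapses are recorded on interim forms.

Patients whose records cannot be built (missing origin, missing current
follow-up date or status, unknown label, or a follow-up before the origin)
are excluded with an explicit reason; exclusions feed the data-quality
report and are never silent.
"""

from __future__ import annotations

import csv
import datetime as dt
import hashlib
import hmac
import io
from dataclasses import dataclass, field, fields as dc_fields

from .dates import ImpreciseDate, years_between
from .model import (
    DEFAULT_MAPPINGS,
    FollowUpForm,
    FormDocument,
    StatusMapping,
    VocabularyError,
)

#: Fixed CSV schema for pseudonymized survival exports.
CSV_COLUMNS = (
    "patient_id",
    "department",
    "diagnosis_date",
    "therapy_date",
    "followup_date",
    "status_label",
    "os_event",
    "efs_event",
    "time_years",
    "efs_time_years",
    "entry_mode",
    "study",
    "source",
    "group",
)


def map_status(
    department: str, status_label: str, mapping: StatusMapping
) -> tuple[int, int]:
    """Return the ``(os_flag, efs_flag)`` pair for a status label.

    Raises :class:`~followkit.model.VocabularyError` listing the valid
    labels for an unknown label, and ``ValueError`` when the mapping does
    not belong to the department.
    """
    if mapping.department != department:
        raise ValueError(
            f"mapping is for department {mapping.department!r}, "
            f"not {department!r}"
        )
    return mapping.flags(status_label)


def _dedup_key(form: FollowUpForm) -> tuple[dt.date, int, str]:
    # Forms without a follow-up date sort first (never "most current").
    resolved = (
        form.followup_date.resolve()
        if form.followup_date is not None
        else dt.date.min
    )
    return (resolved, form.entry_timestamp, form.form_id)


def deduplicate(
    forms: list[FollowUpForm],
) -> tuple[FollowUpForm, list[FollowUpForm]]:
    """Select the most current form of one patient.

    Returns ``(current_form, history)`` where history is all forms sorted
    ascending by resolved follow-up date (ties: entry timestamp, then form
    id) and ``current_form`` is the last element.  Idempotent and invariant
    under permutation of the input order.
    """
    if not forms:
        raise ValueError("deduplicate requires at least one form")
    patients = {f.patient_pseudonym for f in forms}
    if len(patients) > 1:
        raise ValueError(
            f"deduplicate operates on one patient's forms; got {sorted(patients)}"
        )
    history = sorted(forms, key=_dedup_key)
    return history[-1], history


@dataclass(frozen=True)
class SurvivalRecord:
    """Analysis-ready survival row for one patient.

    ``time_years`` is the OS observation time (origin to current follow-up
    contact); ``efs_time_years`` is the time to the first EFS event or to
    the current contact when no event occurred.  Invariants:
    ``0 <= efs_time_years <= time_years`` and a death (``os_event=1``) is
    always an EFS event too.
    """

    patient_pseudonym: str
    department: str
    origin_date: dt.date
    last_contact_date: dt.date
    time_years: float
    os_event: int
    efs_event: int
    efs_time_years: float
    group: str | None = None
    diagnosis_date: ImpreciseDate | None = None
    therapy_date: ImpreciseDate | None = None
    followup_date: ImpreciseDate | None = None
    status_label: str | None = None
    entry_mode: str = "routine"
    study: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if self.time_years < 0:
            raise ValueError("time_years must be non-negative")
        if self.efs_time_years < 0 or self.efs_time_years > self.time_years + 1e-12:
            raise ValueError("efs_time_years must be in [0, time_years]")
        if self.os_event == 1 and self.efs_event != 1:
            raise ValueError("a death must also count as an EFS event")


@dataclass(frozen=True)
class Exclusion:
    """A patient dropped from analysis, with the reason why."""

    patient_pseudonym: str
    reason: str


@dataclass
class BuildResult:
    records: list[SurvivalRecord] = field(default_factory=list)
    exclusions: list[Exclusion] = field(default_factory=list)


def build_record(
    forms: list[FollowUpForm],
    mapping: StatusMapping,
    origin: str = "therapy",
    group: str | None = None,
) -> SurvivalRecord:
    """Build the survival record of one patient from all their forms.

    The origin date is the earliest resolved therapy (or diagnosis) date
    across the patient's forms.  OS time runs to the most current follow-up
    contact with the current status's OS flag as event indicator; EFS time
    runs to the earliest form whose status is EFS-positive, or to the
    current contact with no event.

    Raises ``ValueError`` with a reason suitable for exclusion reporting
    when the record cannot be built.
    """
    if origin not in ("therapy", "diagnosis"):
        raise ValueError(f"origin must be 'therapy' or 'diagnosis', got {origin!r}")
    current, history = deduplicate(forms)

    date_attr = "therapy_date" if origin == "therapy" else "diagnosis_date"
    origin_candidates = [
        getattr(f, date_attr).resolve()
        for f in history
        if getattr(f, date_attr) is not None
    ]
    if not origin_candidates:
        raise ValueError(f"missing {origin} date")
    origin_date = min(origin_candidates)

    if current.followup_date is None:
        raise ValueError("missing follow-up date on current form")
    if current.status_label is None:
        raise ValueError("missing follow-up status on current form")
    last_contact = current.followup_date.resolve()
    if last_contact < origin_date:
        raise ValueError(
            f"follow-up {last_contact.isoformat()} precedes origin "
            f"{origin_date.isoformat()}"
        )

    os_event, efs_event_current = mapping.flags(current.status_label)
    time_years = years_between(origin_date, last_contact)

    # First EFS-positive form (relapse or death) among dated, labelled forms.
    efs_date: dt.date | None = None
    for form in history:
        if form.status_label is None or form.followup_date is None:
            continue
        _, efs_flag = mapping.flags(form.status_label)
        if efs_flag == 1:
            candidate = form.followup_date.resolve()
            if candidate >= origin_date and (efs_date is None or candidate < efs_date):
                efs_date = candidate
    if efs_date is not None:
        efs_event = 1
        efs_time = years_between(origin_date, min(efs_date, last_contact))
    else:
        efs_event = 0
        efs_time = time_years

    return SurvivalRecord(
        patient_pseudonym=current.patient_pseudonym,
        department=current.department,
        origin_date=origin_date,
        last_contact_date=last_contact,
        time_years=time_years,
        os_event=os_event,
        efs_event=max(efs_event, efs_event_current),
        efs_time_years=min(efs_time, time_years),
        group=group,
        diagnosis_date=current.diagnosis_date,
        therapy_date=current.therapy_date,
        followup_date=current.followup_date,
        status_label=current.status_label,
        entry_mode=current.entry_mode,
        study=current.study,
        source=current.source,
    )


def build_records(
    document: FormDocument,
    mappings: dict[str, StatusMapping] | None = None,
    origin: str = "therapy",
    group_by: str | None = None,
) -> BuildResult:
    """Build one survival record per patient of a document.

    ``group_by`` optionally names a form attribute (e.g. ``"study"`` or
    ``"department"``) whose value on the current form becomes the record's
    group label.  Patients that cannot be analysed are collected as
    exclusions with their reason.
    """
    mappings = mappings if mappings is not None else (document.code_lists or DEFAULT_MAPPINGS)
    result = BuildResult()
    for patient, forms in document.forms_by_patient().items():
        department = forms[0].department
        mapping = mappings.get(department)
        if mapping is None:
            result.exclusions.append(
                Exclusion(patient, f"no status mapping for department {department!r}")
            )
            continue
        group = None
        if group_by is not None:
            current, _ = deduplicate(forms)
            group = getattr(current, group_by, None)
        try:
            result.records.append(build_record(forms, mapping, origin, group))
        except (ValueError, VocabularyError) as exc:
            result.exclusions.append(Exclusion(patient, str(exc)))
    return result


# ---------------------------------------------------------------------------
# CSV export / import


def _csv_cell(record: SurvivalRecord, column: str) -> str:
    if column == "patient_id":
        return record.patient_pseudonym
    if column in ("diagnosis_date", "therapy_date", "followup_date"):
        value = getattr(record, column)
        return value.isoformat() if value is not None else ""
    if column in ("time_years", "efs_time_years"):
        # shortest round-tripping representation keeps re-imports exact
        return repr(getattr(record, column))
    value = getattr(record, column)
    return "" if value is None else str(value)


def export_csv(records: list[SurvivalRecord], pseudonym_key: bytes | None = None) -> str:
    """Serialize records to the fixed pseudonymized CSV schema.

    Rows are ordered by patient pseudonym for determinism.  When
    ``pseudonym_key`` is given, patient identifiers are replaced by a
    stable keyed hash (HMAC-SHA256, 16 hex chars) so exports can be
    re-pseudonymized without a lookup table.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    for record in sorted(records, key=lambda r: r.patient_pseudonym):
        row = [_csv_cell(record, c) for c in CSV_COLUMNS]
        if pseudonym_key is not None:
            row[0] = hmac.new(
                pseudonym_key, row[0].encode(), hashlib.sha256
            ).hexdigest()[:16]
        writer.writerow(row)
    return buf.getvalue()


def read_csv(text: str) -> list[SurvivalRecord]:
    """Parse the CSV schema back into records (inverse of export_csv)."""
    reader = csv.DictReader(io.StringIO(text))
    missing = set(CSV_COLUMNS) - set(reader.fieldnames or ())
    if missing:
        raise ValueError(f"CSV lacks required columns: {sorted(missing)}")
    records = []
    for row in reader:
        therapy = row["therapy_date"] or None
        diagnosis = row["diagnosis_date"] or None
        followup = row["followup_date"] or None
        time_years = float(row["time_years"])
        origin_src = therapy or diagnosis
        if origin_src is None:
            raise ValueError(f"row for {row['patient_id']!r} has no origin date")
        followup_date = ImpreciseDate.parse(followup) if followup else None
        origin_date = ImpreciseDate.parse(origin_src).resolve()
        last_contact = (
            followup_date.resolve()
            if followup_date is not None
            else origin_date + dt.timedelta(days=round(time_years * 365.25))
        )
        records.append(
            SurvivalRecord(
                patient_pseudonym=row["patient_id"],
                department=row["department"],
                origin_date=origin_date,
                last_contact_date=last_contact,
                time_years=time_years,
                os_event=int(row["os_event"]),
                efs_event=int(row["efs_event"]),
                efs_time_years=float(row["efs_time_years"]),
                group=row["group"] or None,
                diagnosis_date=ImpreciseDate.parse(diagnosis) if diagnosis else None,
                therapy_date=ImpreciseDate.parse(therapy) if therapy else None,
                followup_date=followup_date,
                status_label=row["status_label"] or None,
                entry_mode=row["entry_mode"] or "routine",
                study=row["study"] or None,
                source=row["source"] or None,
            )
        )
    return records


_RECORD_FIELDS = tuple(f.name for f in dc_fields(SurvivalRecord))
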