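"""Domain types for generic oncological follow-up documentation.

A single generic form covers the survival-relevant core that the urology
(prostate cancer) and haematology (AML) follow-up sheets share: patient
identity, initial diagnosis, initial therapy, study participation and the
follow-up contact itself (date, status, information source).  Department
specifics live entirely in the status and study vocabularies, so one data
model serves both diseases.

For Kaplan-Meier analysis only two binary endpoints matter: overall
survival (OS, death from any cause) and event-free survival (EFS, relapse
or death).  Each department's detailed status list is therefore mapped
unambiguously to an ``(os_flag, efs_flag)`` pair by a
:class:`StatusMapping`.  Every death status is both an OS and an EFS event,
hence the structural invariant ``os_flag == 1  =>  efs_flag == 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .dates import ImpreciseDate

ENTRY_MODES = ("routine", "retrospective")


class VocabularyError(KeyError):
    """A status label does not resolve against its department's code list."""

    def __init__(self, message: str):
        super().__init__(message)
        self.message = message

    def __str__(self) -> str:
        return self.message


class ValidationError(ValueError):
    """A domain-type invariant is violated."""


@dataclass(frozen=True)
class StatusMapping:
    """Department-specific mapping of status labels to OS/EFS event flags."""

    department: str
    entries: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        labels = [label for label, _, _ in self.entries]
        if len(set(labels)) != len(labels):
            raise ValidationError(
                f"duplicate status labels in department {self.department!r}"
            )
        for label, os_flag, efs_flag in self.entries:
            if os_flag not in (0, 1) or efs_flag not in (0, 1):
                raise ValidationError(f"flags for {label!r} must be 0/1")
            if os_flag == 1 and efs_flag != 1:
                raise ValidationError(
                    f"status {label!r}: a death (OS event) must also be an "
                    f"EFS event"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.entries)

    def flags(self, status_label: str) -> tuple[int, int]:
        """Return ``(os_flag, efs_flag)`` for a label.

        Raises :class:`VocabularyError` listing the valid labels when the
        label is not in this department's code list.  Matching is exact.
        """
        for label, os_flag, efs_flag in self.entries:
            if label == status_label:
                return os_flag, efs_flag
        raise VocabularyError(
            f"status label {status_label!r} not in code list of department "
            f"{self.department!r}; valid labels: {', '.join(self.labels)}"
        )

    def __contains__(self, status_label: str) -> bool:
        return any(label == status_label for label, _, _ in self.entries)


# Published status vocabularies of the two pilot departments.  Relapse
# statuses are EFS events only; every death is an OS and an EFS event.
HAEMATOLOGY_MAPPING = StatusMapping(
    department="haematology",
    entries=(
        ("Initial diagnosis", 0, 0),
        ("Aplasia", 0, 0),
        ("First remission", 0, 0),
        ("Complete remission unconfirmed", 0, 0),
        ("Second remission", 0, 0),
        ("Relapse", 0, 1),
        ("Persistent AML", 0, 1),
        ("Death of AML", 1, 1),
        ("Death independent from AML", 1, 1),
        ("Death of unknown cause", 1, 1),
    ),
)

UROLOGY_MAPPING = StatusMapping(
    department="urology",
    entries=(
        ("Initial diagnosis", 0, 0),
        ("Relapse free", 0, 0),
        ("Relapse (PSA)", 0, 1),
        ("Relapse (imaging)", 0, 1),
        ("Death of prostate cancer", 1, 1),
        ("Death independent from prostate cancer", 1, 1),
        ("Death of unknown cause", 1, 1),
    ),
)

DEFAULT_MAPPINGS: dict[str, StatusMapping] = {
    m.department: m for m in (HAEMATOLOGY_MAPPING, UROLOGY_MAPPING)
}

DEFAULT_STUDY_LISTS: dict[str, tuple[str, ...]] = {
    "haematology": ("AMLCG", "observational"),
    "urology": ("prostate registry", "observational"),
}


@dataclass(frozen=True)
class FollowUpForm:
    """One documentation event for one patient.

    The 13-attribute common core: patient identity (pseudonym, department),
    diagnosis (date, text, classification), therapy (date, text,
    classification), study participation, and follow-up data (date, status,
    source, entry mode).  ``entry_timestamp`` and ``form_id`` are plumbing
    used for deduplication tie-breaks and uniqueness.
    """

    patient_pseudonym: str
    department: str
    form_id: str
    diagnosis_date: ImpreciseDate | None = None
    diagnosis_text: str | None = None
    diagnosis_classification: str | None = None
    therapy_date: ImpreciseDate | None = None
    therapy_text: str | None = None
    therapy_classification: str | None = None
    study: str | None = None
    followup_date: ImpreciseDate | None = None
    status_label: str | None = None
    source: str | None = None
    entry_mode: str = "routine"
    entry_timestamp: int = 0

    def __post_init__(self) -> None:
        if self.entry_mode not in ENTRY_MODES:
            raise ValidationError(
                f"entry_mode {self.entry_mode!r} must be one of {ENTRY_MODES}"
            )

    def with_fields(self, **kwargs) -> "FollowUpForm":
        return replace(self, **kwargs)


@dataclass
class FormDocument:
    """An ordered collection of follow-up forms plus their code lists.

    ``code_lists`` maps department name to its :class:`StatusMapping`;
    ``study_lists`` maps department name to its study vocabulary.
    ``metadata`` carries document identifiers and per-item opaque concept
    annotation codes (e.g. SNOMED CT); they are never interpreted.
    """

    forms: list[FollowUpForm] = field(default_factory=list)
    code_lists: dict[str, StatusMapping] = field(default_factory=dict)
    study_lists: dict[str, tuple[str, ...]] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)
    item_annotations: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        """Check document invariants; raise on the first violation."""
        seen: set[str] = set()
        for form in self.forms:
            if form.form_id in seen:
                raise ValidationError(f"duplicate form_id {form.form_id!r}")
            seen.add(form.form_id)
            if form.department not in self.code_lists:
                raise ValidationError(
                    f"form {form.form_id!r}: department {form.department!r} "
                    f"is not configured in the document code lists"
                )
            if form.status_label is not None:
                mapping = self.code_lists[form.department]
                if form.status_label not in mapping:
                    raise VocabularyError(
                        f"form {form.form_id!r}: status label "
                        f"{form.status_label!r} not in code list of "
                        f"department {form.department!r}; valid labels: "
                        f"{', '.join(mapping.labels)}"
                    )

    def forms_by_patient(self) -> dict[str, list[FollowUpForm]]:
        """Group forms by patient pseudonym, preserving document order."""
        out: dict[str, list[FollowUpForm]] = {}
        for form in self.forms:
            out.setdefault(form.patient_pseudonym, []).append(form)
        return out
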