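"""Status mapping, deduplication and survival-record construction."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from followkit.dates import ImpreciseDate
from followkit.harmonize import (
    build_record,
    build_records,
    deduplicate,
    export_csv,
    map_status,
    read_csv,
)
from followkit.model import (
    DEFAULT_MAPPINGS,
    HAEMATOLOGY_MAPPING,
    UROLOGY_MAPPING,
    StatusMapping,
    ValidationError,
    VocabularyError,
)

from conftest import make_document, make_form


class TestMapStatus:
    @pytest.mark.parametrize(
        "department, label, expected",
        [
            ("urology", "Relapse (PSA)", (0, 1)),
            ("urology", "Relapse (imaging)", (0, 1)),
            ("urology", "Initial diagnosis", (0, 0)),
            ("urology", "Relapse free", (0, 0)),
            ("urology", "Death of prostate cancer", (1, 1)),
            ("urology", "Death of unknown cause", (1, 1)),
            ("haematology", "Death of AML", (1, 1)),
            ("haematology", "Persistent AML", (0, 1)),
            ("haematology", "First remission", (0, 0)),
            ("haematology", "Aplasia", (0, 0)),
        ],
    )
    def test_published_vocabulary(self, department, label, expected):
        mapping = DEFAULT_MAPPINGS[department]
        assert map_status(department, label, mapping) == expected

    def test_unknown_label_lists_valid_ones(self, urology_mapping):
        with pytest.raises(VocabularyError) as err:
            map_status("urology", "Remission", urology_mapping)
        assert "Relapse (PSA)" in str(err.value)

    def test_department_mismatch(self, urology_mapping):
        with pytest.raises(ValueError):
            map_status("haematology", "Relapse", urology_mapping)

    @pytest.mark.parametrize("mapping", [UROLOGY_MAPPING, HAEMATOLOGY_MAPPING])
    def test_death_implies_efs_event(self, mapping):
        """OS-positive labels are a subset of EFS-positive labels."""
        os_labels = {l for l, o, _ in mapping.entries if o == 1}
        efs_labels = {l for l, _, e in mapping.entries if e == 1}
        assert os_labels <= efs_labels

    def test_mapping_invariant_enforced_on_construction(self):
        with pytest.raises(ValidationError):
            StatusMapping("x", (("Death, lost EFS flag", 1, 0),))


class TestDeduplicate:
    def test_single_form_identity(self):
        form = make_form()
        current, history = deduplicate([form])
        assert current == form and history == [form]
        # idempotent
        assert deduplicate([current])[0] == current

    def test_latest_followup_date_wins(self):
        relapse = make_form(
            form_id="F1",
            followup_date=ImpreciseDate(2009, 1, 1),
            status_label="Relapse (PSA)",
        )
        death = make_form(
            form_id="F2",
            followup_date=ImpreciseDate(2010, 1, 1),
            status_label="Death of prostate cancer",
        )
        current, history = deduplicate([death, relapse])
        assert current.status_label == "Death of prostate cancer"
        assert [f.form_id for f in history] == ["F1", "F2"]

    def test_tie_breaks(self):
        a = make_form(form_id="F1", entry_timestamp=0)
        b = make_form(form_id="F2", entry_timestamp=5)
        assert deduplicate([a, b])[0].form_id == "F2"  # later timestamp
        c = make_form(form_id="F3", entry_timestamp=5)
        assert deduplicate([b, c])[0].form_id == "F3"  # larger form_id

    @settings(max_examples=50, derandomize=True)
    @given(perm=st.permutations(range(5)))
    def test_permutation_invariance(self, perm):
        forms = [
            make_form(
                form_id=f"F{i}",
                followup_date=ImpreciseDate(2000 + i % 3, 6, 1),
                entry_timestamp=i,
            )
            for i in range(5)
        ]
        shuffled = [forms[i] for i in perm]
        assert deduplicate(shuffled) == deduplicate(forms)

    def test_rejects_multiple_patients(self):
        with pytest.raises(ValueError):
            deduplicate([make_form(pid="P1"), make_form(pid="P2")])


class TestBuildRecord:
    def test_five_year_death(self, urology_mapping):
        form = make_form(
            therapy_date=ImpreciseDate(2000, 1, 1),
            followup_date=ImpreciseDate(2005, 1, 1),
            status_label="Death of prostate cancer",
        )
        record = build_record([form], urology_mapping)
        assert record.time_years == pytest.approx(1827 / 365.25)
        assert round(record.time_years, 2) == 5.0
        assert record.os_event == 1 and record.efs_event == 1
        assert record.efs_time_years == record.time_years

    def test_zero_duration_boundary(self, urology_mapping):
        form = make_form(
            therapy_date=ImpreciseDate(2000, 1, 1),
            followup_date=ImpreciseDate(2000, 1, 1),
            status_label="Initial diagnosis",
        )
        record = build_record([form], urology_mapping)
        assert record.time_years == 0.0
        assert record.os_event == 0

    def test_efs_first_event_rule(self, urology_mapping):
        relapse = make_form(
            form_id="F1",
            followup_date=ImpreciseDate(2003, 1, 1),
            status_label="Relapse (PSA)",
        )
        alive = make_form(
            form_id="F2",
            followup_date=ImpreciseDate(2008, 1, 1),
            status_label="Relapse free",
        )
        record = build_record([relapse, alive], urology_mapping)
        origin = dt.date(2000, 1, 1)
        assert record.os_event == 0
        assert record.time_years == pytest.approx(
            (dt.date(2008, 1, 1) - origin).days / 365.25
        )
        assert record.efs_event == 1
        assert record.efs_time_years == pytest.approx(
            (dt.date(2003, 1, 1) - origin).days / 365.25
        )

    def test_origin_is_earliest_across_forms(self, urology_mapping):
        early = make_form(form_id="F1", therapy_date=ImpreciseDate(1999, 5, 2))
        late = make_form(
            form_id="F2",
            therapy_date=ImpreciseDate(2001, 1, 1),
            followup_date=ImpreciseDate(2006, 1, 1),
            entry_timestamp=1,
        )
        record = build_record([early, late], urology_mapping)
        assert record.origin_date == dt.date(1999, 5, 2)

    def test_diagnosis_origin_flag(self, urology_mapping):
        form = make_form()
        record = build_record([form], urology_mapping, origin="diagnosis")
        assert record.origin_date == dt.date(1999, 11, 20)

    @pytest.mark.parametrize(
        "overrides, reason_match",
        [
            (dict(therapy_date=None), "therapy"),
            (dict(followup_date=None), "follow-up date"),
            (dict(status_label=None), "status"),
            (
                dict(followup_date=ImpreciseDate(1990, 1, 1)),
                "precedes origin",
            ),
        ],
    )
    def test_unbuildable_patients_are_excluded_with_reason(
        self, overrides, reason_match
    ):
        doc = make_document([make_form(**overrides)])
        result = build_records(doc)
        assert result.records == []
        assert len(result.exclusions) == 1
        assert reason_match in result.exclusions[0].reason

    def test_invariants_on_simulated_cohort(self, clean_cohort):
        result = build_records(clean_cohort)
        # dedup conservation: every patient yields exactly one record
        assert len(result.records) == 200 and not result.exclusions
        for r in result.records:
            assert 0 <= r.efs_time_years <= r.time_years + 1e-12
            if r.os_event == 1:
                assert r.efs_event == 1


class TestCsv:
    def test_empty_export_is_header_only(self):
        text = export_csv([])
        assert text.splitlines() == [
            "patient_id,department,diagnosis_date,therapy_date,followup_date,"
            "status_label,os_event,efs_event,time_years,efs_time_years,"
            "entry_mode,study,source,group"
        ]

    def test_roundtrip_three_records(self, urology_mapping):
        forms = [
            make_form(
                pid=f"P{i}",
                form_id=f"F{i}",
                followup_date=ImpreciseDate(2004 + i, 3, 1),
                status_label=status,
            )
            for i, status in enumerate(
                ["Relapse free", "Relapse (PSA)", "Death of unknown cause"]
            )
        ]
        records = [build_record([f], urology_mapping) for f in forms]
        back = read_csv(export_csv(records))
        assert back == sorted(records, key=lambda r: r.patient_pseudonym)

    def test_group_column_optional(self, urology_mapping):
        record = build_record([make_form()], urology_mapping, group="G1")
        lines = export_csv([record]).splitlines()
        assert lines[1].endswith(",G1")
        no_group = build_record([make_form()], urology_mapping)
        assert export_csv([no_group]).splitlines()[1].endswith(",")

    def test_keyed_pseudonymization_is_stable(self, urology_mapping):
        record = build_record([make_form()], urology_mapping)
        a = export_csv([record], pseudonym_key=b"k1")
        b = export_csv([record], pseudonym_key=b"k1")
        c = export_csv([record], pseudonym_key=b"k2")
        assert a == b
        assert a != c
        assert "P1," not in a
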