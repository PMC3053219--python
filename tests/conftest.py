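import datetime as dt

import numpy as np
import pytest

from followkit.dates import ImpreciseDate
from followkit.model import (
    DEFAULT_MAPPINGS,
    FollowUpForm,
    FormDocument,
    UROLOGY_MAPPING,
)
from followkit.simulate import CohortSpec, simulate_cohort


@pytest.fixture
def urology_mapping():
    return UROLOGY_MAPPING


@pytest.fixture
def four_record_arrays():
    """The hand-computed worked example: event, censor, event, censor."""
    return np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 0, 1, 0])


def make_form(pid="P1", form_id="F1", **kwargs):
    defaults = dict(
        patient_pseudonym=pid,
        department="urology",
        form_id=form_id,
        diagnosis_date=ImpreciseDate(1999, 11, 20),
        therapy_date=ImpreciseDate(2000, 1, 1),
        followup_date=ImpreciseDate(2005, 1, 1),
        status_label="Relapse free",
        entry_mode="routine",
        entry_timestamp=0,
    )
    defaults.update(kwargs)
    return FollowUpForm(**defaults)


@pytest.fixture
def form_factory():
    return make_form


def make_document(forms):
    return FormDocument(forms=list(forms), code_lists=dict(DEFAULT_MAPPINGS))


@pytest.fixture
def document_factory():
    return make_document


@pytest.fixture(scope="session")
def small_cohort():
    """A 50-patient simulated cohort shared across tests."""
    return simulate_cohort(CohortSpec(n_patients=50, seed=7))


@pytest.fixture(scope="session")
def clean_cohort():
    """200 patients, no missingness, no imprecise dates."""
    return simulate_cohort(
        CohortSpec(
            n_patients=200,
            seed=11,
            missing_therapy_date=0.0,
            missing_status=0.0,
            missing_followup_date=0.0,
            imprecise_date_rate=0.0,
        )
    )


@pytest.fixture
def study_end():
    return dt.date(2010, 5, 31)
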