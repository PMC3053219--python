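"""Kaplan-Meier estimator, confidence bands, medians and risk counts.

The estimator is checked three independent ways: a hand-computed
product-limit worked example, the empirical survivor function on
censoring-free inputs, and frozen reference values computed once with
R ``survival::survfit`` (conf.type="log") on a fixed 25-subject dataset.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from followkit.km import (
    km_fit,
    median_survival,
    numbers_at_risk,
    survival_at,
    survival_at_ci,
)

# ---------------------------------------------------------------------------
# Fixed 25-subject dataset and the R survival::survfit reference values
# (conf.type="log", 95%) computed independently and frozen.

ORACLE_TIME = np.array(
    [8.116, 0.668, 0.193, 0.794, 3.787, 0.045, 0.678, 0.595, 0.908, 5.533,
     1.969, 1.959, 1.277, 4.498, 0.38, 8.297, 8.812, 2.818, 4.511, 2.804,
     0.841, 11.872, 2.986, 4.127, 1.291]
)
ORACLE_EVENT = np.array(
    [1, 1, 1, 1, 0, 1, 1, 0, 0, 1, 1, 0, 1, 0, 0, 0, 0, 1, 1, 0, 0, 0, 1,
     1, 1]
)
# columns: time, n_risk, n_event, n_censor, surv, lower, upper
R_SURVFIT = np.array([
    [0.045, 25, 1, 0, 0.960000000000, 0.8861782272999, 1.000000000000],
    [0.193, 24, 1, 0, 0.920000000000, 0.8195712195373, 1.000000000000],
    [0.380, 23, 0, 1, 0.920000000000, 0.8195712195373, 1.000000000000],
    [0.595, 22, 0, 1, 0.920000000000, 0.8195712195373, 1.000000000000],
    [0.668, 21, 1, 0, 0.876190476190, 0.7541242081899, 1.000000000000],
    [0.678, 20, 1, 0, 0.832380952381, 0.6948446952278, 0.997140878595],
    [0.794, 19, 1, 0, 0.788571428571, 0.6395856802767, 0.972262070799],
    [0.841, 18, 0, 1, 0.788571428571, 0.6395856802767, 0.972262070799],
    [0.908, 17, 0, 1, 0.788571428571, 0.6395856802767, 0.972262070799],
    [1.277, 16, 1, 0, 0.739285714286, 0.5788426905445, 0.944200170918],
    [1.291, 15, 1, 0, 0.690000000000, 0.5217255973796, 0.912548670012],
    [1.959, 14, 0, 1, 0.690000000000, 0.5217255973796, 0.912548670012],
    [1.969, 13, 1, 0, 0.636923076923, 0.4622319664783, 0.877635116861],
    [2.804, 12, 0, 1, 0.636923076923, 0.4622319664783, 0.877635116861],
    [2.818, 11, 1, 0, 0.579020979021, 0.3995207410073, 0.839168683211],
    [2.986, 10, 1, 0, 0.521118881119, 0.3407908007334, 0.796866839346],
    [3.787, 9, 0, 1, 0.521118881119, 0.3407908007334, 0.796866839346],
    [4.127, 8, 1, 0, 0.455979020979, 0.2768490207175, 0.751011750138],
    [4.498, 7, 0, 1, 0.455979020979, 0.2768490207175, 0.751011750138],
    [4.511, 6, 1, 0, 0.379982517483, 0.2056349073099, 0.702150794732],
    [5.533, 5, 1, 0, 0.303986013986, 0.1429645127405, 0.646366674693],
    [8.116, 4, 1, 0, 0.227989510490, 0.0887936994651, 0.585393076382],
    [8.297, 3, 0, 1, 0.227989510490, 0.0887936994651, 0.585393076382],
    [8.812, 2, 0, 1, 0.227989510490, 0.0887936994651, 0.585393076382],
    [11.872, 1, 0, 1, 0.227989510490, 0.0887936994651, 0.585393076382],
])


class TestWorkedExample:
    """Hand product-limit computation on event@1, censor@2, event@3, censor@4."""

    def test_survival_and_greenwood(self, four_record_arrays):
        times, events = four_record_arrays
        curve = km_fit(times=times, events=events)
        assert curve.survival == pytest.approx([0.75, 0.75, 0.375, 0.375])
        # Greenwood: S(1)^2 * 1/(4*3); S(3)^2 * (1/12 + 1/(2*1))
        assert curve.variance[0] == pytest.approx(0.75**2 / 12)
        assert curve.variance[2] == pytest.approx(0.375**2 * 7 / 12)
        assert list(curve.n_risk) == [4, 3, 2, 1]

    def test_median_is_three(self, four_record_arrays):
        times, events = four_record_arrays
        assert median_survival(km_fit(times=times, events=events)) == 3.0

    def test_step_function_evaluation(self, four_record_arrays):
        times, events = four_record_arrays
        curve = km_fit(times=times, events=events)
        assert survival_at(curve, 0.0) == 1.0
        assert survival_at(curve, 2.0) == 0.75  # carried from t=1
        assert survival_at(curve, 100.0) == 0.375  # extension beyond data
        with pytest.raises(ValueError):
            survival_at(curve, -1.0)

    def test_numbers_at_risk(self, four_record_arrays):
        times, _ = four_record_arrays
        counts = numbers_at_risk(times, [0.0, 2.5, 10.0])
        assert list(counts) == [4, 2, 0]


def test_matches_frozen_r_survfit_values():
    """S(t), at-risk/event/censor counts and log-transform CI match R."""
    curve = km_fit(
        times=ORACLE_TIME, events=ORACLE_EVENT, ci_transform="log"
    )
    assert np.allclose(curve.times, R_SURVFIT[:, 0])
    assert np.array_equal(curve.n_risk, R_SURVFIT[:, 1])
    assert np.allclose(curve.survival, R_SURVFIT[:, 4], atol=1e-10)
    assert np.allclose(curve.ci_low, R_SURVFIT[:, 5], atol=1e-9)
    assert np.allclose(curve.ci_high, R_SURVFIT[:, 6], atol=1e-9)
    assert median_survival(curve) == pytest.approx(4.127)


def test_no_events_degenerate_curve():
    curve = km_fit(times=[1.0, 2.0, 3.0], events=[0, 0, 0])
    assert np.all(curve.survival == 1.0)
    assert np.all(curve.variance == 0.0)
    assert np.all(curve.ci_low == 1.0) and np.all(curve.ci_high == 1.0)
    assert median_survival(curve) is None  # "not reached"


def test_all_events_reach_zero():
    curve = km_fit(times=[1.0, 2.0], events=[1, 1])
    assert curve.survival[-1] == 0.0
    assert 0.0 <= curve.ci_low[-1] <= curve.ci_high[-1] <= 1.0


def test_empty_input_is_an_error():
    with pytest.raises(ValueError):
        km_fit(times=[], events=[])


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    data=st.lists(
        st.tuples(st.floats(0.01, 50.0), st.integers(0, 1)),
        min_size=1,
        max_size=60,
    )
)
def test_invariants_hold_on_random_inputs(data):
    times = np.array([t for t, _ in data])
    events = np.array([e for _, e in data])
    curve = km_fit(times=times, events=events)
    assert np.all(np.diff(curve.survival) <= 1e-12)  # non-increasing
    assert np.all(curve.ci_low <= curve.survival + 1e-12)
    assert np.all(curve.survival <= curve.ci_high + 1e-12)
    assert np.all((curve.ci_low >= 0) & (curve.ci_high <= 1))
    # risk-set bookkeeping
    n_next = curve.n_risk - curve.n_event - curve.n_censor
    assert np.array_equal(n_next[:-1], curve.n_risk[1:])
    # Greenwood variance of log S is non-decreasing while the estimate is
    # positive (at S=0 the curve has collapsed and the sum is undefined)
    alive = curve.survival > 0
    gw = curve.variance[alive] / curve.survival[alive] ** 2
    assert np.all(np.diff(gw) >= -1e-12)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    times=st.lists(st.floats(0.01, 50.0), min_size=1, max_size=60),
    c=st.floats(0.1, 10.0),
)
def test_no_censoring_equals_empirical_survivor_and_scale_equivariance(times, c):
    times = np.array(times)
    events = np.ones(len(times), dtype=int)
    curve = km_fit(times=times, events=events)
    for t in np.unique(times):
        empirical = np.mean(times > t)  # independent brute-force oracle
        assert survival_at(curve, t) == pytest.approx(empirical, abs=1e-12)
    scaled = km_fit(times=c * times, events=events)
    assert np.allclose(scaled.times, c * curve.times)
    assert np.allclose(scaled.survival, curve.survival)


def test_tied_events_processed_before_censorings():
    # one event and one censoring at t=2: the censored subject still counts
    # in the risk set for the event at 2
    curve = km_fit(times=[1.0, 2.0, 2.0, 3.0], events=[0, 1, 0, 1])
    i = list(curve.times).index(2.0)
    assert curve.n_risk[i] == 3
    assert curve.survival[i] == pytest.approx(2 / 3)


def test_median_plateau_rule():
    # S hits exactly 0.5 at t=1 and stays: median is the smallest such t
    curve = km_fit(times=[1.0, 1.0, 2.0, 3.0], events=[1, 1, 0, 0])
    assert median_survival(curve) == 1.0


def test_exponential_median_recovery():
    """n=5000 exponential cohort, lambda=0.1/y: median within 5% of ln2/0.1."""
    rng = np.random.default_rng(42)
    n, lam = 5000, 0.1
    event_times = rng.exponential(1 / lam, n)
    censor_times = rng.uniform(0, 30, n)  # administrative-style censoring
    times = np.minimum(event_times, censor_times)
    events = (event_times <= censor_times).astype(int)
    curve = km_fit(times=times, events=events)
    median = median_survival(curve)
    assert median == pytest.approx(np.log(2) / lam, rel=0.05)


def test_survival_at_ci_consistent(four_record_arrays):
    times, events = four_record_arrays
    curve = km_fit(times=times, events=events)
    s, lo, hi = survival_at_ci(curve, 3.5)
    assert s == 0.375 and lo <= s <= hi
    assert survival_at_ci(curve, 0.0) == (1.0, 1.0, 1.0)
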