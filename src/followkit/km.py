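"""Kaplan-Meier estimation, Greenwood confidence bands and log-rank tests.

The product-limit estimator is computed from first principles.  With
:math:`n_i` subjects at risk just before the i-th distinct observed time
and :math:`d_i` events at that time,

.. math::  \\hat S(t) = \\prod_{t_i \\le t} \\left(1 - d_i / n_i\\right),

with Greenwood's variance estimate

.. math::  \\widehat{\\mathrm{Var}}[\\hat S(t)]
           = \\hat S(t)^2 \\sum_{t_i \\le t} \\frac{d_i}{n_i (n_i - d_i)}.

At tied times events are processed before censorings, i.e. subjects
censored at :math:`t_i` are still in the risk set for events at
:math:`t_i`.  Confidence intervals default to the log transform (a
symmetric normal interval on :math:`\\log \\hat S`, the convention of the
reference R implementation); plain and log-log transforms are available.

The log-rank test compares groups by the hypergeometric model: at each
distinct event time the expected events in group ``g`` are
:math:`e_{gj} = n_{gj} d_j / n_j`, with the multivariate hypergeometric
covariance; the statistic is a quadratic form of observed-minus-expected
over the first :math:`g-1` groups, referred to a chi-square distribution
with :math:`g-1` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonize import SurvivalRecord

CI_TRANSFORMS = ("plain", "log", "log-log")


def records_to_arrays(
    records: list[SurvivalRecord], endpoint: str = "os"
) -> tuple[np.ndarray, np.ndarray]:
    """Extract (time, event) arrays for an endpoint from survival records."""
    if endpoint == "os":
        times = np.array([r.time_years for r in records], dtype=float)
        events = np.array([r.os_event for r in records], dtype=int)
    elif endpoint == "efs":
        times = np.array([r.efs_time_years for r in records], dtype=float)
        events = np.array([r.efs_event for r in records], dtype=int)
    else:
        raise ValueError(f"endpoint must be 'os' or 'efs', got {endpoint!r}")
    return times, events


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate over the distinct observed times.

    ``survival[i]`` is the estimate just after ``times[i]``; the estimate
    before the first time is 1.  ``n_risk[i]`` counts subjects at risk
    just before ``times[i]`` (subjects censored at a time still count for
    events at that same time).
    """

    times: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    n_censor: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    conf_level: float = 0.95
    endpoint: str = "os"

    @property
    def median(self) -> float | None:
        return median_survival(self)

    def survival_at(self, t: float) -> float:
        return survival_at(self, t)

    def to_table(self):
        """Curve as a pandas DataFrame (time, counts, estimate, CI)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "n_censor": self.n_censor,
                "survival": self.survival,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _km_ci(
    survival: np.ndarray,
    gw_sum: np.ndarray,
    conf_level: float,
    transform: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Confidence limits for S(t); gw_sum is the Greenwood cumulative sum."""
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        if transform == "plain":
            half = z * survival * np.sqrt(gw_sum)
            low, high = survival - half, survival + half
        elif transform == "log":
            # Var(log S) = Var(S)/S^2 = gw_sum by the delta method.
            se_log = np.sqrt(gw_sum)
            low = survival * np.exp(-z * se_log)
            high = survival * np.exp(z * se_log)
        elif transform == "log-log":
            # "exponential Greenwood": normal interval on log(-log S).
            log_s = np.log(survival)
            se_cll = np.sqrt(gw_sum) / np.abs(log_s)
            low = survival ** np.exp(z * se_cll)
            high = survival ** np.exp(-z * se_cll)
        else:
            raise ValueError(
                f"ci_transform must be one of {CI_TRANSFORMS}, got {transform!r}"
            )
    # S == 1 (no events yet): the interval is degenerate at 1.
    low = np.where(survival >= 1.0, 1.0, low)
    high = np.where(survival >= 1.0, 1.0, high)
    # S == 0: estimate has collapsed; report a degenerate interval.
    low = np.where(survival <= 0.0, 0.0, low)
    high = np.where(survival <= 0.0, 0.0, high)
    return np.clip(low, 0.0, 1.0), np.clip(high, 0.0, 1.0)


def km_fit(
    records=None,
    endpoint: str = "os",
    conf_level: float = 0.95,
    ci_transform: str = "log",
    *,
    times=None,
    events=None,
) -> KMCurve:
    """Fit a Kaplan-Meier curve.

    Accepts either ``records`` (a list of :class:`SurvivalRecord`, with
    ``endpoint`` selecting OS or EFS) or raw ``times``/``events`` arrays.
    Event indicators are 1 for an observed event, 0 for censoring.
    """
    if records is not None:
        times, events = records_to_arrays(records, endpoint)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("km_fit requires at least one observation")
    if np.any(times < 0):
        raise ValueError("observation times must be non-negative")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")
    if not 0 < conf_level < 1:
        raise ValueError("conf_level must be in (0, 1)")

    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq, start = np.unique(times, return_index=True)
    k = uniq.size
    n_event = np.zeros(k, dtype=int)
    n_censor = np.zeros(k, dtype=int)
    bounds = np.append(start, times.size)
    for i in range(k):
        block = events[bounds[i] : bounds[i + 1]]
        n_event[i] = int(block.sum())
        n_censor[i] = block.size - n_event[i]
    n_risk = times.size - np.concatenate(([0], np.cumsum(n_event + n_censor)[:-1]))

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - n_event / n_risk
        survival = np.cumprod(frac)
        # Greenwood increments only at event times; n == d ends the curve
        # at S = 0 where the variance sum diverges — masked to 0 there.
        inc = np.where(
            (n_event > 0) & (n_risk > n_event),
            n_event / (n_risk * (n_risk - n_event).clip(min=1)),
            0.0,
        )
        gw_sum = np.cumsum(inc)
        variance = survival**2 * gw_sum

    ci_low, ci_high = _km_ci(survival, gw_sum, conf_level, ci_transform)
    return KMCurve(
        times=uniq,
        n_risk=n_risk,
        n_event=n_event,
        n_censor=n_censor,
        survival=survival,
        variance=variance,
        ci_low=ci_low,
        ci_high=ci_high,
        conf_level=conf_level,
        endpoint=endpoint,
    )


def median_survival(curve: KMCurve) -> float | None:
    """Smallest time with S(t) <= 0.5, or ``None`` when never reached."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if below.size == 0:
        return None
    return float(curve.times[below[0]])


def survival_at(curve: KMCurve, t: float) -> float:
    """Right-continuous step-function evaluation of the estimate at t."""
    if t < 0:
        raise ValueError("time must be non-negative")
    idx = np.searchsorted(curve.times, t, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.survival[idx])


def survival_at_ci(curve: KMCurve, t: float) -> tuple[float, float, float]:
    """Estimate with confidence limits at time t."""
    if t < 0:
        raise ValueError("time must be non-negative")
    idx = np.searchsorted(curve.times, t, side="right") - 1
    if idx < 0:
        return 1.0, 1.0, 1.0
    return (
        float(curve.survival[idx]),
        float(curve.ci_low[idx]),
        float(curve.ci_high[idx]),
    )


def numbers_at_risk(times, at_times) -> np.ndarray:
    """Count of subjects with observation time >= t, per requested t.

    ``times`` may be raw observation times or a list of records (OS times).
    """
    if len(times) and isinstance(times[0], SurvivalRecord):
        times = [r.time_years for r in times]
    times = np.asarray(times, dtype=float)
    at_times = np.asarray(at_times, dtype=float)
    if np.any(at_times < 0):
        raise ValueError("risk-table times must be non-negative")
    return (times[None, :] >= at_times[:, None]).sum(axis=1)


@dataclass(frozen=True)
class LogRankResult:
    """Log-rank comparison of survival across groups."""

    groups: tuple[str, ...]
    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    df: int
    p_value: float

    def __str__(self) -> str:  # pragma: no cover - convenience
        return (
            f"log-rank chi2 = {self.statistic:.4g} on {self.df} df, "
            f"p = {self.p_value:.4g}"
        )


def logrank_test(
    times, events, group_labels=None, *, records=None, endpoint: str = "os"
) -> LogRankResult:
    """Multi-group log-rank test of equal survival distributions.

    Call either with raw arrays ``(times, events, group_labels)`` or with
    ``records=`` plus ``group_labels`` (or records carrying ``group``).
    Uses the hypergeometric expected events and covariance at each
    distinct event time; the statistic is a quadratic form with a
    generalized inverse of the (g-1)-dimensional covariance block.
    """
    if records is not None:
        if group_labels is None:
            group_labels = [r.group for r in records]
        times, events = records_to_arrays(records, endpoint)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(group_labels, dtype=object)
    if labels.size != times.size:
        raise ValueError("every record needs a group label")
    if any(lbl is None for lbl in labels):
        raise ValueError("every record needs a group label")

    group_names = tuple(sorted({str(lbl) for lbl in labels}))
    g = len(group_names)
    if g < 2:
        raise ValueError("log-rank test requires at least 2 groups")
    group_idx = np.array([group_names.index(str(lbl)) for lbl in labels])

    event_times = np.unique(times[events == 1])
    observed = np.zeros(g)
    expected = np.zeros(g)
    cov = np.zeros((g, g))
    for t in event_times:
        at_risk = times >= t
        n_j = at_risk.sum()
        event_here = at_risk & (times == t) & (events == 1)
        d_j = event_here.sum()
        n_gj = np.bincount(group_idx[at_risk], minlength=g).astype(float)
        d_gj = np.bincount(group_idx[event_here], minlength=g).astype(float)
        observed += d_gj
        expected += n_gj * d_j / n_j
        if n_j > 1:
            scale = d_j * (n_j - d_j) / (n_j - 1)
            p = n_gj / n_j
            cov += scale * (np.diag(p) - np.outer(p, p))

    diff = (observed - expected)[: g - 1]
    v = cov[: g - 1, : g - 1]
    statistic = float(diff @ np.linalg.pinv(v) @ diff) if v.any() else 0.0
    df = g - 1
    p_value = float(stats.chi2.sf(statistic, df)) if statistic > 0 else 1.0
    return LogRankResult(
        groups=group_names,
        observed=observed,
        expected=expected,
        statistic=statistic,
        df=df,
        p_value=p_value,
    )
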