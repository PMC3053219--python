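"""Kaplan-Meier plots with confidence bands and numbers-at-risk tables.

Layout follows the convention of clinical survival reports: a step-function
curve per group with a shaded confidence band, and beneath the time axis
one row of at-risk counts per group, aligned to the axis ticks.  Only the
structural content is pinned down; fonts and colours follow matplotlib
defaults.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .km import KMCurve, numbers_at_risk


def _step_arrays(curve: KMCurve) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Prepend the (0, 1) origin so the step starts at full survival."""
    t = np.concatenate(([0.0], curve.times))
    s = np.concatenate(([1.0], curve.survival))
    lo = np.concatenate(([1.0], curve.ci_low))
    hi = np.concatenate(([1.0], curve.ci_high))
    return t, s, lo, hi


def render_km_plot(
    curves: dict[str, KMCurve],
    risk_times: list[float],
    group_times: dict[str, np.ndarray],
    title: str = "",
    xlabel: str = "Years",
    annotation: str | None = None,
    ax=None,
):
    """Render one or more KM curves with a numbers-at-risk table.

    ``group_times`` maps each curve label to the raw observation times used
    to compute at-risk counts at ``risk_times``.  Returns the figure.
    """
    if not curves:
        raise ValueError("render_km_plot requires at least one curve")
    risk_times = list(risk_times)
    if ax is None:
        fig, ax = plt.subplots(figsize=(7.0, 5.5))
    else:
        fig = ax.figure

    for label, curve in curves.items():
        t, s, lo, hi = _step_arrays(curve)
        (line,) = ax.step(t, s, where="post", label=label)
        ax.fill_between(
            t, lo, hi, step="post", alpha=0.2, color=line.get_color()
        )
    ax.set_ylim(0.0, 1.05)
    ax.set_xlim(left=0.0)
    ax.set_ylabel("Survival probability")
    ax.set_xlabel(xlabel)
    if title:
        ax.set_title(title)
    if len(curves) > 1:
        ax.legend(loc="lower left", fontsize="small")
    if annotation:
        ax.annotate(
            annotation,
            xy=(0.97, 0.95),
            xycoords="axes fraction",
            ha="right",
            va="top",
            fontsize="small",
        )

    # Numbers-at-risk rows beneath the axis, one per group.
    xmin, xmax = ax.get_xlim()
    span = max(xmax - xmin, 1e-9)
    header_y = -0.16
    ax.text(
        -0.02,
        header_y,
        "At risk",
        transform=ax.transAxes,
        ha="right",
        va="center",
        fontsize="small",
        fontweight="bold",
    )
    for row, (label, _) in enumerate(curves.items()):
        y = header_y - 0.06 * (row + 1)
        counts = numbers_at_risk(group_times[label], risk_times)
        ax.text(
            -0.02,
            y,
            label if len(curves) > 1 else "n",
            transform=ax.transAxes,
            ha="right",
            va="center",
            fontsize="small",
        )
        for t, count in zip(risk_times, counts):
            ax.text(
                (t - xmin) / span,
                y,
                str(int(count)),
                transform=ax.transAxes,
                ha="center",
                va="center",
                fontsize="small",
            )
    fig.subplots_adjust(bottom=0.18 + 0.05 * len(curves))
    return fig


def completeness_page(report_rows: list[dict], title: str = "Data quality"):
    """Render the completeness report as a table figure for the PDF."""
    fig, ax = plt.subplots(figsize=(7.0, 5.5))
    ax.axis("off")
    ax.set_title(title)
    if not report_rows:
        ax.text(0.5, 0.5, "no data", ha="center")
        return fig
    columns = list(report_rows[0].keys())
    cells = [[str(row[c]) for c in columns] for row in report_rows]
    table = ax.table(
        cellText=cells, colLabels=columns, loc="upper center", cellLoc="center"
    )
    table.auto_set_font_size(False)
    table.set_fontsize(8)
    return fig
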