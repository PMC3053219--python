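"""End-to-end pipeline: forms → records → curves → quality → PDF report.

Mirrors the clinical workflow of exporting follow-up documentation and
running a batch survival analysis: parse or simulate a form document,
deduplicate and harmonize to survival records, fit Kaplan-Meier curves
per endpoint (with grouped comparison and log-rank test when a grouping
attribute is given), compute the completeness report, and bundle plots,
tables and a machine-readable run summary into an output directory with
a single PDF.

Every stage logs its counts to stderr and exclusions are reported, never
silent; parsed = analyzed + excluded holds per endpoint.
"""

from __future__ import annotations

import datetime as dt
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

from matplotlib.backends.backend_pdf import PdfPages

from . import harmonize, km, odm, quality
from .plotting import completeness_page, render_km_plot
from .simulate import CohortSpec, simulate_cohort

ENDPOINTS = ("os", "efs")

#: Default evaluation times (years) for risk tables and survival summaries.
DEFAULT_RISK_TIMES = (0.0, 5.0, 10.0, 15.0)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    input_path: str | None = None
    mapping_path: str | None = None
    origin: str = "therapy"
    endpoints: tuple[str, ...] = ("os", "efs")
    group_by: str | None = None
    conf_level: float = 0.95
    risk_times: tuple[float, ...] = DEFAULT_RISK_TIMES
    study_end: dt.date | None = None
    output_dir: str = "followkit-report"
    seed: int = 0
    simulate: CohortSpec | None = None

    def validate(self) -> None:
        if not self.endpoints:
            raise ValueError("at least one endpoint is required")
        for endpoint in self.endpoints:
            if endpoint not in ENDPOINTS:
                raise ValueError(
                    f"unknown endpoint {endpoint!r}; valid: {ENDPOINTS}"
                )
        if not 0 < self.conf_level < 1:
            raise ValueError("conf_level must be in (0, 1)")
        if self.origin not in ("therapy", "diagnosis"):
            raise ValueError("origin must be 'therapy' or 'diagnosis'")
        if self.input_path is None and self.simulate is None:
            raise ValueError("either an input path or a simulation spec is required")


def _log(stage: str, message: str) -> None:
    print(f"[{stage}] {message}", file=sys.stderr)


def load_mappings(path: str):
    """Read a status-mapping file (JSON or YAML) mirroring the code lists."""
    import yaml

    from .model import StatusMapping

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    mappings = {}
    for department, entries in raw.items():
        mappings[department] = StatusMapping(
            department=department,
            entries=tuple(
                (e["label"], int(e["os"]), int(e["efs"])) for e in entries
            ),
        )
    return mappings


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run summary dict."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- input stage -------------------------------------------------------
    if config.simulate is not None:
        doc = simulate_cohort(config.simulate)
        _log("simulate", f"generated {len(doc.forms)} forms")
        odm.write_odm_file(doc, str(out / "cohort.odm.xml"))
    else:
        doc = odm.read_odm(config.input_path)
        _log("parse", f"read {len(doc.forms)} forms from {config.input_path}")
    by_patient = doc.forms_by_patient()
    _log("parse", f"{len(doc.forms)} forms over {len(by_patient)} patients")

    mappings = (
        load_mappings(config.mapping_path)
        if config.mapping_path
        else (doc.code_lists or None)
    )

    # --- harmonize stage ---------------------------------------------------
    build = harmonize.build_records(
        doc, mappings, origin=config.origin, group_by=config.group_by
    )
    n_patients = len(by_patient)
    _log(
        "harmonize",
        f"{n_patients} patients -> {len(build.records)} records, "
        f"{len(build.exclusions)} excluded",
    )
    for exc in build.exclusions:
        _log("exclude", f"{exc.patient_pseudonym}: {exc.reason}")
    (out / "records.csv").write_text(
        harmonize.export_csv(build.records), encoding="utf-8"
    )

    summary: dict = {
        "seed": config.seed,
        "counts": {
            "forms": len(doc.forms),
            "patients": n_patients,
            "analyzed": len(build.records),
            "excluded": len(build.exclusions),
        },
        "exclusions": [
            {"patient": e.patient_pseudonym, "reason": e.reason}
            for e in build.exclusions
        ],
        "endpoints": {},
    }

    # --- analysis stage ----------------------------------------------------
    figures = []
    for endpoint in config.endpoints:
        curve = km.km_fit(
            build.records, endpoint=endpoint, conf_level=config.conf_level
        )
        curve.to_table().to_csv(out / f"curve_{endpoint}.csv", index=False)
        median = km.median_survival(curve)
        ep_summary = {
            "n": len(build.records),
            "events": int(curve.n_event.sum()),
            "median_years": median,
            "survival_at": {
                str(t): km.survival_at(curve, t) for t in (5.0, 10.0)
            },
        }
        _log(
            "analyze",
            f"{endpoint}: {ep_summary['events']} events, median "
            f"{'not reached' if median is None else f'{median:.2f} y'}",
        )
        times, _ = km.records_to_arrays(build.records, endpoint)
        fig = render_km_plot(
            {endpoint.upper(): curve},
            list(config.risk_times),
            {endpoint.upper(): times},
            title=f"{endpoint.upper()} — all patients",
        )
        figures.append(fig)

        if config.group_by is not None:
            groups = sorted(
                {r.group for r in build.records if r.group is not None}
            )
            if len(groups) >= 2:
                grouped = [r for r in build.records if r.group is not None]
                result = km.logrank_test(
                    None, None, records=grouped, endpoint=endpoint
                )
                ep_summary["logrank"] = {
                    "groups": list(result.groups),
                    "statistic": result.statistic,
                    "df": result.df,
                    "p_value": result.p_value,
                }
                _log(
                    "analyze",
                    f"{endpoint} grouped by {config.group_by}: {result}",
                )
                curves, group_times = {}, {}
                for group in groups:
                    members = [r for r in grouped if r.group == group]
                    curves[group] = km.km_fit(
                        members,
                        endpoint=endpoint,
                        conf_level=config.conf_level,
                    )
                    group_times[group], _ = km.records_to_arrays(
                        members, endpoint
                    )
                fig = render_km_plot(
                    curves,
                    list(config.risk_times),
                    group_times,
                    title=f"{endpoint.upper()} by {config.group_by}",
                    annotation=f"log-rank p = {result.p_value:.3g}",
                )
                figures.append(fig)
        summary["endpoints"][endpoint] = ep_summary

    # --- quality stage -----------------------------------------------------
    currents = quality.current_forms(by_patient)
    report = quality.full_report(
        currents,
        records=build.records,
        study_end=config.study_end,
        eligible_patient_ids=set(by_patient),
        all_forms=doc.forms,
    )
    (out / "completeness.csv").write_text(report.to_csv(), encoding="utf-8")
    total = report.strata["total"]
    _log(
        "quality",
        f"all-three completeness {total.all_three_percentage}% "
        f"({total.all_three_count}/{total.case_count})",
    )
    summary["completeness"] = {
        "rows": report.to_rows(),
        "clark_c": report.clark_c,
    }
    figures.append(completeness_page(report.to_rows()))

    # --- report stage ------------------------------------------------------
    pdf_path = out / "report.pdf"
    with PdfPages(pdf_path) as pdf:
        for fig in figures:
            pdf.savefig(fig)
    import matplotlib.pyplot as plt

    plt.close("all")
    (out / "run_summary.json").write_text(
        json.dumps(summary, indent=2, default=str), encoding="utf-8"
    )
    _log("report", f"wrote {pdf_path}")
    return summary
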