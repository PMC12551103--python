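"""End-to-end pipeline: generate/load -> cut-offs -> screen -> counterfactuals
-> equity, with deterministic outputs and provenance headers.

Every stage CSV carries a ``# config_hash=...`` comment header so any output
file traces back to the exact configuration that produced it; identical
config and seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .cutoffs import kit_summary, seasonal_summary
from .equity import or_table
from .fixtures import make_table1_fixture
from .registry import load_registry, write_registry
from .screening import (
    classify_cohort,
    cohort_summary,
    counterfactual_cutoffs,
    counterfactual_panels,
    load_panel,
)
from .cohort import generate_cohort

log = logging.getLogger("cfnbs")

__all__ = ["RunReport", "StageFailure", "run_pipeline", "render_report", "config_hash"]


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.__cause__ = cause


def config_hash(config: RunConfig) -> str:
    """Stable hash of a run configuration (key order independent)."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All pipeline outputs as plain JSON-serialisable tables."""

    provenance: dict
    outcome_counts: dict
    cohort_summary: list
    counterfactual_cutoffs: list
    seasonal_summary: dict
    kit_summary: list
    panel_detection: list
    equity_or: list
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunReport":
        return cls(**data)


def _write_csv(df: pd.DataFrame, path: Path, chash: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage of the configured run; see module docstring."""
    chash = config_hash(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level.upper())

    def stage(name, fn, *args, **kwargs):
        log.info("stage %s: starting", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageFailure(name, exc) from exc

    # --- cohort ----------------------------------------------------------
    if config.cohort.fixture:
        registry = stage("cohort", make_table1_fixture)
    elif config.cohort.registry is not None:
        registry = stage("cohort", load_registry, config.cohort.registry)
    else:
        params = config.cohort.params.model_copy(update={"seed": config.seed})
        registry = stage("cohort", generate_cohort, params)
    log.info("cohort: %d records, %d with CF", len(registry), int(registry["has_cf"].sum()))
    _write_csv(registry.assign(
        specimen_date=registry["specimen_date"].dt.strftime("%Y-%m-%d"),
        diagnosis_date=pd.to_datetime(registry["diagnosis_date"]).dt.strftime("%Y-%m-%d").fillna(""),
    ), outdir / "registry.csv", chash)

    panels = [stage("panels", load_panel, p) for p in config.panels]
    strategies = config.strategy_models()

    # --- screening under the first (primary) strategy ---------------------
    classified = stage("screen", classify_cohort, registry, panels[0], strategies[0])
    counts = classified["category"].value_counts().to_dict()
    summary = stage("summary", cohort_summary, classified)

    # --- cut-off series summaries -----------------------------------------
    floating = next((s for s in strategies if s.mode != "fixed"), None)
    if floating is not None:
        series_model = floating
    else:
        from .cutoffs import CutoffModel

        series_model = CutoffModel(mode="floating", percentile=95.0)
    series = stage("percentiles", lambda: series_model.fit(registry).daily_series_)
    season = seasonal_summary(series) if series is not None and len(series) else {}
    kits = stage("kits", kit_summary, registry, series_model.percentile, series_model.trim_threshold)

    # --- counterfactuals ---------------------------------------------------
    cf_cutoffs = stage("evaluate-cutoffs", counterfactual_cutoffs, registry, strategies, panels[0])
    missed_gen = classified[classified["category"] == "missed_genetics"]
    if len(missed_gen):
        _, panel_summary = stage("evaluate-panels", counterfactual_panels, missed_gen, panels)
    else:
        panel_summary = pd.DataFrame(
            columns=["panel", "n_cases", "n_ge1", "n_eq2", "frac_ge1", "frac_eq2"])

    # --- equity ------------------------------------------------------------
    equity = stage("equity", or_table, classified)

    _write_csv(summary, outdir / "cohort_summary.csv", chash)
    if series is not None:
        _write_csv(series, outdir / "daily_cutoffs.csv", chash)
    _write_csv(kits, outdir / "kit_summary.csv", chash)
    _write_csv(cf_cutoffs, outdir / "counterfactual_cutoffs.csv", chash)
    _write_csv(panel_summary, outdir / "panel_detection.csv", chash)
    _write_csv(equity, outdir / "equity_or.csv", chash)

    report = RunReport(
        provenance={
            "config_hash": chash,
            "seed": config.seed,
            "version": __version__,
            "n_records": int(len(registry)),
            "strategies": list(config.strategies),
            "panels": [p.name for p in panels],
        },
        outcome_counts={k: int(v) for k, v in sorted(counts.items())},
        cohort_summary=summary.to_dict(orient="records"),
        counterfactual_cutoffs=cf_cutoffs.to_dict(orient="records"),
        seasonal_summary=season,
        kit_summary=kits.to_dict(orient="records"),
        panel_detection=panel_summary.to_dict(orient="records"),
        equity_or=equity.to_dict(orient="records"),
        warnings=[] if len(registry) else ["empty cohort"],
    )
    (outdir / "report.json").write_text(render_report(report, "json"), encoding="utf-8")
    (outdir / "report.md").write_text(render_report(report, "markdown"), encoding="utf-8")
    return report


def _md_table(rows: list[dict]) -> str:
    if not rows:
        return "_(no rows)_\n"
    cols = list(rows[0])
    out = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for row in rows:
        cells = []
        for c in cols:
            v = row[c]
            cells.append(f"{v:.3g}" if isinstance(v, float) else str(v))
        out.append("| " + " | ".join(cells) + " |")
    return "\n".join(out) + "\n"


def render_report(report: RunReport, format: str = "markdown") -> str:
    """Render a run report as schema-stable JSON or human-readable markdown."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True)
    if format != "markdown":
        raise ValueError(f"unknown report format {format!r}")

    p = report.provenance
    counts = report.outcome_counts
    cf_total = sum(v for k, v in counts.items() if k != "not_cf")
    missed = counts.get("missed_low_irt", 0) + counts.get("missed_genetics", 0)
    lines = [
        "# Newborn-screening run report",
        "",
        f"- config hash: `{p['config_hash']}`  seed: {p['seed']}  version: {p['version']}",
        f"- records: {p['n_records']}  strategies: {', '.join(p['strategies'])}"
        f"  panels: {', '.join(p['panels'])}",
        "",
    ]
    if report.warnings:
        lines += ["## Warnings", ""] + [f"- {w}" for w in report.warnings] + [""]
    lines += ["## Outcomes", ""]
    for k, v in counts.items():
        lines.append(f"- {k}: {v}")
    if cf_total:
        lines.append(
            f"- missed (false negative): {missed} of {cf_total} CF cases "
            f"({100 * missed / cf_total:.1f}%)"
        )
    lines += ["", "## Demographics", "", _md_table(report.cohort_summary)]
    lines += ["## Cut-off counterfactuals", "", _md_table(report.counterfactual_cutoffs)]
    if report.seasonal_summary:
        lines += ["## Seasonal mean daily cut-offs", ""]
        lines += [f"- {s}: {v:.2f} ng/mL" for s, v in report.seasonal_summary.items()]
        lines += [""]
    lines += ["## Reagent kits", "", _md_table(report.kit_summary)]
    lines += ["## Panel detection among genetics-missed cases", "", _md_table(report.panel_detection)]
    lines += ["## Equity odds ratios", "", _md_table(report.equity_or)]
    return "\n".join(lines)
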