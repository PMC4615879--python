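"""End-to-end pipeline: cohort in, summary tables and projections out.

Two entry modes:

* **cohort mode** — a patient-level table (CSV path or ``"synthetic"``) is
  summarized, the adjusted-cost GLM is fitted, and the summary feeds the
  savings projection;
* **frame mode** — aggregate counts and the excess cost are supplied
  directly (no patient-level data), and only the projection stages run.

Outputs in ``output_dir``: ``summary.csv`` (group x procedure
descriptives), ``projection.csv`` (per-procedure and overall savings),
``glm.json`` (adjusted-cost model and LS-means), ``roi_bed_days.json``,
and ``manifest.json`` (full configuration, for reproducibility). The same
configuration always produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .adjusted import fit_gamma_glm, ls_means
from .cohort import read_cohort
from .descriptives import (compare_costs, compare_los, compare_readmission,
                           summaries_to_frame, summarize)
from .projection import (EffectSize, ProcedureSavingsRow, StudyFrame,
                         frame_from_summaries, per_procedure_savings,
                         procedure_frames_from_summaries, project_savings)
from .roi import ImplementationCost, roi_bed_day_report
from .synthetic import default_spec, generate_cohort

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """An invalid configuration field, raised before any computation."""


@dataclass
class RunConfig:
    """Pipeline configuration; defaults reproduce the headline analysis."""

    input: str = "synthetic"          # "synthetic" or a cohort CSV path
    scale: float = 1.0                # synthetic-cohort shrink factor
    seed: int = 0
    or_low: float = 0.71
    or_high: float = 0.83
    interpretation: str = "count_scaling"
    period_years: float = 2.5
    excess_los: float = 3.0
    avg_los: float = 5.0
    implementation_cost: ImplementationCost = field(default_factory=ImplementationCost)
    output_dir: str = "gdft_report"
    # frame mode: aggregate inputs instead of a patient table
    frame_n_total: int | None = None
    frame_n_complications: int | None = None
    frame_cost_diff: float | None = None
    fit_glm: bool = True
    glm_include_procedure: bool = False
    strict_read: bool = False

    def effect(self) -> EffectSize:
        return EffectSize(self.or_low, self.or_high, self.interpretation)

    def frame_mode(self) -> bool:
        return self.frame_n_total is not None

    def validate(self) -> None:
        try:
            self.effect()
        except ValueError as exc:
            raise ConfigError(f"effect size: {exc}") from None
        if not 0 < self.scale <= 1:
            raise ConfigError(f"scale must be in (0, 1], got {self.scale}")
        if self.period_years <= 0:
            raise ConfigError("period_years must be positive")
        if self.excess_los <= 0 or self.avg_los <= 0:
            raise ConfigError("excess_los and avg_los must be positive")
        frame_fields = (self.frame_n_total, self.frame_n_complications,
                        self.frame_cost_diff)
        if any(f is not None for f in frame_fields) and any(f is None for f in frame_fields):
            raise ConfigError("frame mode needs frame_n_total, "
                              "frame_n_complications and frame_cost_diff together")
        if self.input != "synthetic" and not self.frame_mode():
            if not Path(self.input).exists():
                raise ConfigError(f"input cohort file not found: {self.input}")


def load_config(path) -> RunConfig:
    """Read a YAML/JSON config file into a :class:`RunConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    impl = raw.pop("implementation_cost", None)
    cfg = RunConfig(**raw)
    if impl is not None:
        try:
            cfg.implementation_cost = ImplementationCost(**impl)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"implementation_cost: {exc}") from None
    return cfg


def _projection_frame(rows: list[ProcedureSavingsRow],
                      overall: ProcedureSavingsRow | None) -> pd.DataFrame:
    all_rows = ([overall] if overall else []) + rows
    return pd.DataFrame([{
        "procedure": r.procedure,
        "n": r.n,
        "morbidity_pct": r.morbidity,
        "cost_diff": r.cost_diff,
        "savings_per_patient_low": r.savings_per_patient_low,
        "savings_per_patient_high": r.savings_per_patient_high,
        "savings_per_year_low": round(r.savings_per_year_low, 2),
        "savings_per_year_high": round(r.savings_per_year_high, 2),
    } for r in all_rows])


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the results."""
    config.validate()
    effect = config.effect()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    if config.frame_mode():
        frame = StudyFrame(config.frame_n_total, config.frame_n_complications,
                           config.frame_cost_diff, config.period_years)
        proc_rows: list[ProcedureSavingsRow] = []
    else:
        if config.input == "synthetic":
            records = generate_cohort(default_spec(seed=config.seed),
                                      scale=config.scale)
        else:
            records = read_cohort(config.input, strict=config.strict_read)
        logger.info("cohort: %d records", len(records))
        summaries = summarize(records, by_procedure=True)
        summaries_to_frame(summaries).to_csv(outdir / "summary.csv", index=False,
                                             lineterminator="\n")
        results["comparisons"] = {
            c.quantity: {"test": c.test, "statistic": c.statistic, "p_value": c.p_value}
            for c in (compare_costs(records), compare_los(records),
                      compare_readmission(records))
        }
        frame = frame_from_summaries(summaries, period_years=config.period_years)
        proc_rows = per_procedure_savings(procedure_frames_from_summaries(summaries),
                                          effect, period_years=config.period_years)
        if config.fit_glm:
            model = fit_gamma_glm(records,
                                  include_procedure=config.glm_include_procedure)
            lsm = ls_means(model)
            glm_doc = {"model": model.to_dict(), "ls_means": lsm.to_dict()}
            results["glm"] = glm_doc
            _write_json(glm_doc, outdir / "glm.json")

    projection = project_savings(frame, effect)
    results["frame"] = dataclasses.asdict(frame)
    results["projection"] = projection.to_dict()

    overall_row = ProcedureSavingsRow(
        procedure="All", n=frame.n_total,
        morbidity=round(100.0 * frame.morbidity, 1),
        cost_diff=frame.cost_diff,
        savings_per_patient_low=projection.savings_per_patient_low,
        savings_per_patient_high=projection.savings_per_patient_high,
        savings_per_year_low=projection.savings_per_year_low,
        savings_per_year_high=projection.savings_per_year_high,
    )
    _projection_frame(proc_rows, overall_row).to_csv(
        outdir / "projection.csv", index=False, lineterminator="\n")

    report = roi_bed_day_report(
        projection.savings_per_patient_low, projection.savings_per_patient_high,
        n_complications=frame.n_complications, effect=effect,
        cost=config.implementation_cost, excess_los=config.excess_los,
        avg_los=config.avg_los, period_years=config.period_years,
        n_total=frame.n_total)
    results["roi_bed_days"] = report.to_dict()
    _write_json(report.to_dict(), outdir / "roi_bed_days.json")

    manifest = {
        "config": _config_dict(config),
        "versions": {"gdft_impact": __version__},
    }
    _write_json(manifest, outdir / "manifest.json")
    results["manifest"] = manifest
    return results


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
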