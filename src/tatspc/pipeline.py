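"""End-to-end analysis pipeline.

For each available TAT component (overall, wet-lab, dry-lab) the
pipeline runs both learning-curve regressions, the residual CUSUM with
its phase report, the EWMA chart and the paired Bernoulli LLR charts
(deterioration OR = 1.20, improvement OR = 1/1.20) at the component's
clinical threshold (42 days overall, 21 days per component).  Every
default the run resolves (reference mean E, baseline exceedance
probability p0, smoothing weight, control limit, smoothing window) is
echoed in the report, so a report is self-describing; given the same
seed and inputs the report bundle is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import charts, phases, regression
from .charts import DETERIORATION_ODDS_RATIO
from .series import COMPONENTS, TATSeries, ValidationError, read_tat_csv
from .synthetic import SyntheticConfig, generate_tat_series

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "DEFAULT_THRESHOLDS"]

#: clinical exceedance thresholds in days: 6 weeks overall, 3 weeks per component
DEFAULT_THRESHOLDS = {"overall": 42, "wet": 21, "dry": 21}


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


@dataclass
class PipelineConfig:
    """Configuration of one analysis run.

    Exactly one of ``input_path`` (a TAT CSV) or ``synthetic`` (a
    generator configuration) supplies the series.
    """

    input_path: Optional[str] = None
    synthetic: Optional[SyntheticConfig] = None
    components: tuple[str, ...] = COMPONENTS
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    odds_ratio: float = DETERIORATION_ODDS_RATIO
    lam: float = charts.DEFAULT_LAM
    init_window: int = charts.DEFAULT_INIT_WINDOW
    expected: Optional[float] = None
    p0: Optional[float] = None
    control_limit: Optional[float] = None
    min_run: int = phases.DEFAULT_MIN_RUN
    out_dir: Optional[str] = None


def _load_series(config: PipelineConfig) -> TATSeries:
    if (config.input_path is None) == (config.synthetic is None):
        raise ValidationError("supply exactly one of input_path or synthetic config")
    if config.input_path is not None:
        return read_tat_csv(config.input_path, allow_missing_components=True)
    return generate_tat_series(config.synthetic)


def _analyze_component(series: TATSeries, component: str, config: PipelineConfig, log: list[str]) -> dict:
    threshold = config.thresholds.get(component, DEFAULT_THRESHOLDS[component])
    out: dict = {"threshold_days": threshold}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - stage name must reach the caller
            log.append(f"ERROR {component}/{name}: {exc}")
            raise PipelineStageError(f"{component}/{name}", exc) from exc

    robust = stage("robust_regression", lambda: regression.fit_robust_linear(series, component))
    nb = stage("negative_binomial_regression", lambda: regression.fit_negative_binomial(series, component))
    out["regression"] = {"robust": robust.to_dict(), "negative_binomial": nb.to_dict()}
    log.append(
        f"{component}: robust slope {robust.slope:.5f} days/case; NB IRR {nb.irr:.5f}"
    )

    cusum = stage("cusum", lambda: charts.cusum_chart(series, component, expected=config.expected))
    out["cusum"] = {"expected": cusum.expected, "values": cusum.values.tolist()}
    log.append(f"{component}: CUSUM reference E = {cusum.expected:.4f} days")

    ewma = stage(
        "ewma",
        lambda: charts.ewma_chart(series, component, lam=config.lam, init_window=config.init_window),
    )
    out["ewma"] = {
        "lam": ewma.lam,
        "init_window": ewma.init_window,
        "z0": ewma.z0,
        "values": ewma.values.tolist(),
    }
    log.append(f"{component}: EWMA lam = {ewma.lam}, z0 = {ewma.z0:.4f}")

    report = stage("phases", lambda: phases.segment_trends(cusum, min_run=config.min_run))
    out["phases"] = report.to_dict()
    log.append(
        f"{component}: nadir case {report.nadir_case} (min_run = {report.min_run})"
    )

    def llr_pair():
        y = charts.dichotomize(series, component, threshold_days=threshold)
        pair = charts.odds_ratio_pair(config.odds_ratio)
        kwargs = dict(
            p0=config.p0,
            control_limit=config.control_limit,
            threshold_days=threshold,
            component=component,
        )
        det = charts.cusum_llr_chart(y, pair.deterioration, **kwargs)
        imp = charts.cusum_llr_chart(y, pair.improvement, **kwargs)
        return det, imp

    det, imp = stage("llr", llr_pair)
    out["llr"] = {
        "deterioration": _llr_dict(det),
        "improvement": _llr_dict(imp),
    }
    log.append(
        f"{component}: LLR p0 = {det.p0:.4f} at threshold > {threshold} days; "
        f"odds ratios {det.odds_ratio:.4f} / {imp.odds_ratio:.4f}"
    )
    return out


def _llr_dict(chart: charts.LLRChart) -> dict:
    return {
        "odds_ratio": chart.odds_ratio,
        "p0": chart.p0,
        "threshold_days": chart.threshold_days,
        "control_limit": chart.control_limit,
        "signals": list(chart.signals),
        "values": chart.values.tolist(),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and return (and optionally write) the report bundle."""
    log: list[str] = []
    try:
        series = _load_series(config)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("load", exc) from exc
    log.append(f"loaded series: n = {len(series)}, provenance = {series.provenance}")

    report: dict = {
        "provenance": series.provenance,
        "n_cases": len(series),
        "resolved_defaults": {
            "lam": config.lam,
            "init_window": config.init_window,
            "odds_ratio": config.odds_ratio,
            "control_limit": config.control_limit,
            "min_run": config.min_run,
            "thresholds": {c: config.thresholds.get(c, DEFAULT_THRESHOLDS[c]) for c in config.components},
        },
        "components": {},
    }
    if config.synthetic is not None:
        report["synthetic_config"] = config.synthetic.to_dict()

    for component in config.components:
        if not series.has_component(component):
            log.append(f"{component}: skipped (missing values)")
            report["components"][component] = {"skipped": "missing values"}
            continue
        report["components"][component] = _analyze_component(series, component, config, log)

    report["log"] = log
    if config.out_dir is not None:
        _write_outputs(series, report, config)
    return report


def _write_outputs(series: TATSeries, report: dict, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series.to_csv(out / "series.csv")
    (out / "report.json").write_text(report_json(report), encoding="utf-8")
    (out / "run.log").write_text("\n".join(report["log"]) + "\n", encoding="utf-8")
    for component, comp in report["components"].items():
        if "cusum" not in comp:
            continue
        import pandas as pd

        n = len(comp["cusum"]["values"])
        frame = pd.DataFrame(
            {
                "case_index": np.arange(1, n + 1),
                "cusum": comp["cusum"]["values"],
                "ewma": comp["ewma"]["values"],
                "llr_deterioration": comp["llr"]["deterioration"]["values"],
                "llr_improvement": comp["llr"]["improvement"]["values"],
            }
        )
        frame.to_csv(out / f"{component}_charts.csv", index=False)


def report_json(report: dict) -> str:
    """Deterministic JSON serialization of a report bundle."""
    return json.dumps(report, sort_keys=True, indent=2)
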