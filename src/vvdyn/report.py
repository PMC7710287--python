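"""End-to-end pipeline: simulate or load, stratify, screen, time, report.

``run_full_pipeline`` chains the stages — cohort acquisition (simulation or a
long-format CSV), healthy-variation thresholding, contraction stratification of
the patient arm, the cross-correlation screen on the contracting subset, and
the EAE timing analysis — writing each stage's table next to a single
machine-readable JSON report.  Every number in the report is recomputable from
the stage outputs; the run is deterministic given the seed (the wall-clock
timestamp is isolated in one field).
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import VV, Cohort, read_cohort_csv, write_cohort_csv
from .eaetiming import compare_event_timing, extract_cohort_event_times, kaplan_meier, spearman
from .synthdata import (
    EAECohortConfig,
    MSCohortConfig,
    generate_eae_cohort,
    generate_healthy_cohort,
    generate_ms_cohort,
)
from .tsccf import run_ccf_screen
from .vvevents import DEFAULT_THRESHOLD_PCT, estimate_normal_variation_threshold, stratify_cohort

__all__ = ["PipelineConfig", "run_full_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one end-to-end run.

    Exactly one of ``input_csv`` (a long-format cohort CSV mixing groups) or
    ``simulate=True`` must be set.  Simulation parameters are passed through to
    the generator configs as dicts.
    """

    simulate: bool = True
    input_csv: str | None = None
    healthy: dict = field(default_factory=dict)
    ms: dict = field(default_factory=dict)
    eae: dict = field(default_factory=dict)
    x_variable: str = VV
    y_variables: list[str] | None = None
    max_lag: int = 2
    alpha: float = 0.05
    threshold_mode: str = "fixed"       # "fixed" | "estimate"
    threshold_value: float = DEFAULT_THRESHOLD_PCT
    fdr_pool: str = "all"
    min_duration: int = 2
    screen_group: str = "contracting"   # "contracting" | "all"
    seed: int = 0
    output_dir: str = "vvdyn_out"

    def __post_init__(self) -> None:
        if self.simulate == (self.input_csv is not None):
            raise ValueError("exactly one of simulate / input_csv must be given")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.threshold_mode not in ("fixed", "estimate"):
            raise ValueError("threshold_mode must be 'fixed' or 'estimate'")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls(**data)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="list"))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    return obj


def _split_by_group(cohort: Cohort) -> dict[str, Cohort]:
    groups: dict[str, list] = {}
    for s in cohort:
        groups.setdefault(s.group, []).append(s)
    return {g: Cohort(subjects=subs) for g, subs in groups.items()}


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run simulate/load -> stratify -> screen -> EAE timing; return the report."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    if config.simulate:
        healthy = generate_healthy_cohort(seed=config.seed, **config.healthy)
        ms = generate_ms_cohort(MSCohortConfig(seed=config.seed + 1, **config.ms))
        eae = generate_eae_cohort(EAECohortConfig(seed=config.seed + 2, **config.eae))
        write_cohort_csv(healthy, outdir / "healthy_cohort.csv")
        write_cohort_csv(ms, outdir / "ms_cohort.csv", outdir / "ms_ground_truth.json")
        write_cohort_csv(eae, outdir / "eae_cohort.csv", outdir / "eae_ground_truth.json")
    else:
        by_group = _split_by_group(read_cohort_csv(config.input_csv))
        healthy = by_group.get("healthy", Cohort(subjects=[]))
        ms = by_group.get("ms", Cohort(subjects=[]))
        eae = by_group.get("eae", Cohort(subjects=[]))
    if len(ms) == 0 and len(eae) == 0:
        raise ValueError("cohort is empty: nothing to analyze")

    # --- healthy-variation threshold ---------------------------------------
    if config.threshold_mode == "estimate" and len(healthy) > 0:
        thr = estimate_normal_variation_threshold(healthy)
    else:
        thr = estimate_normal_variation_threshold(None)
        thr.value = config.threshold_value
    report: dict = {
        "version": __version__,
        "timestamp": datetime.datetime.now().isoformat(),
        "config": _jsonify({k: v for k, v in config.__dict__.items()}),
        "cohort_counts": {"healthy": len(healthy), "ms": len(ms), "eae": len(eae)},
        "threshold": {"value": thr.value, "source": thr.source,
                      "per_subject_maxima": thr.per_subject_maxima},
        "warnings": warnings,
    }

    # --- stratification of the patient arm ---------------------------------
    if len(ms) > 0:
        strat = stratify_cohort(ms, threshold=thr.value, min_duration=config.min_duration)
        strat.to_frame().to_csv(outdir / "vv_events.csv", index=False)
        strat.lollipop_frame().to_csv(outdir / "vv_lollipop.csv", index=False)
        report["stratification"] = _jsonify(strat.summary())
        warnings.extend(f"stratification excluded {sid}" for sid in strat.excluded)

        # --- cross-correlation screen ---------------------------------------
        if config.screen_group == "contracting":
            ids = set(strat.contracting_ids)
            screen_cohort = Cohort(subjects=[s for s in ms if s.subject_id in ids])
        else:
            screen_cohort = ms
        if len(screen_cohort) > 0:
            screen = run_ccf_screen(
                screen_cohort,
                x_variable=config.x_variable,
                y_variables=config.y_variables,
                max_lag=config.max_lag,
                alpha=config.alpha,
                fdr_pool=config.fdr_pool,
            )
            screen.to_frame().to_csv(outdir / "ccf_records.csv", index=False)
            summary = screen.summary()
            summary["lollipop"].to_csv(outdir / "ccf_lollipop.csv", index=False)
            summary.pop("lollipop")
            report["screen"] = _jsonify(summary)
            warnings.extend(
                f"ADF did not confirm stationarity: {sid}/{var}"
                for sid, var in screen.adf_failures
            )
            warnings.extend(f"screen skipped {sid}" for sid in screen.skipped_subjects)

    # --- EAE timing ---------------------------------------------------------
    if len(eae) > 0:
        timing = extract_cohort_event_times(eae, vv_threshold=thr.value)
        timing.to_csv(outdir / "eae_timing.csv", index=False)
        curves = []
        from .eaetiming import EVENT_COLUMNS

        for event, (tcol, ccol) in EVENT_COLUMNS.items():
            km = kaplan_meier(timing[tcol].to_numpy(), ~timing[ccol].to_numpy(dtype=bool))
            km.insert(0, "event", event)
            curves.append(km)
        pd.concat(curves, ignore_index=True).to_csv(outdir / "eae_survival.csv", index=False)
        report["eae_timing"] = {
            "n_animals": len(eae),
            "comparisons": _jsonify(compare_event_timing(timing)),
            "median_days": _jsonify(
                {c[0]: float(timing[c[0]].median()) for c in EVENT_COLUMNS.values()}
            ),
        }
        histo = eae.ground_truth.get("histology") if eae.ground_truth else None
        if histo:
            h = pd.DataFrame(histo)
            rho_vv, p_vv = spearman(h["score"].to_numpy(), h["vv_at_sacrifice"].to_numpy())
            rho_dt1, p_dt1 = spearman(h["score"].to_numpy(), h["dt1_at_sacrifice"].to_numpy())
            report["histology"] = {
                "spearman_vv": {"rho": rho_vv, "p": p_vv},
                "spearman_dt1": {"rho": rho_dt1, "p": p_dt1},
            }

    report["warnings"] = warnings
    (outdir / "report.json").write_text(json.dumps(_jsonify(report), indent=1))
    return report
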