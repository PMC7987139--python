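"""End-to-end pipeline: simulate/load -> exclusions -> split -> stack -> fit
-> predict -> validate -> report.

A run writes publication-style CSV tables (baseline characteristics,
hazard-ratio table, per-horizon calibration/discrimination, subgroup
calibration, risk-distribution bins), the serialized model fit, and a
manifest recording versions, per-stage seeds, and stage counts so the run is
reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortTable, apply_exclusions, build_stacked, describe_cohort, load_cohort
from .pc_cox import CovariateSpec, fit_pc_cox, hazard_ratio_table
from .simulate import SimulationConfig, default_config, simulate_cohort
from .validation import DEFAULT_HORIZONS, SplitSpec, split_cohort, validate_model

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "stage_seed"]

log = logging.getLogger("screenrisk")

STAGES = ["load", "simulate", "exclusions", "split", "stack", "fit", "predict", "validate", "report"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global_seed * 1000003 + stage index,
    reduced mod 2^31 (documented so stages can be rerun in isolation)."""
    return (int(global_seed) * 1000003 + STAGES.index(stage)) % (2**31)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    # either simulate ...
    simulation: SimulationConfig | None = None
    # ... or load from CSVs
    visits_path: str | None = None
    outcomes_path: str | None = None
    estimation_fraction: float = 0.6
    horizons: list = field(default_factory=lambda: list(DEFAULT_HORIZONS))
    subgroup_tau: float = 10.0
    smr_method: str = "lognormal"
    export_stacked: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        h = list(self.horizons)
        if h != sorted(h) or any(x <= 0 for x in h):
            raise ValueError("horizons must be sorted and positive")
        if self.simulation is None and (self.visits_path is None or self.outcomes_path is None):
            raise ValueError("either a simulation config or both input CSV paths are required")


def _stage(stage, code, fn, *args, **kw):
    try:
        return fn(*args, **kw)
    except PipelineError:
        raise
    except FileNotFoundError as exc:
        raise PipelineError(stage, "missing_input", str(exc)) from exc
    except Exception as exc:
        raise PipelineError(stage, code, str(exc)) from exc


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    manifest = {
        "screenrisk_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in ["simulate", "split"]},
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k != "simulation"
        },
        "counts": {},
    }

    if config.simulation is not None:
        sim_cfg = config.simulation.replace(seed=stage_seed(config.seed, "simulate"))
        manifest["config"]["simulation"] = sim_cfg.to_dict()
        log.info("simulating cohort of %d women", sim_cfg.n_women)
        cohort = _stage("simulate", "simulation_failed", lambda: simulate_cohort(sim_cfg).cohort)
    else:
        log.info("loading cohort from %s", config.visits_path)
        cohort = _stage("load", "load_failed", load_cohort, config.visits_path, config.outcomes_path)
    manifest["counts"]["women_loaded"] = cohort.n_women
    manifest["counts"]["visits_loaded"] = cohort.n_visits

    cohort = _stage("exclusions", "exclusion_failed", apply_exclusions, cohort)
    manifest["counts"]["women_after_exclusions"] = cohort.n_women
    manifest["counts"]["exclusions"] = cohort.exclusion_log

    table1 = _stage("report", "describe_failed", describe_cohort, cohort)
    table1.to_csv(out / "table1.csv", index=False)

    split = SplitSpec(config.estimation_fraction, stage_seed(config.seed, "split"))
    est, val = _stage("split", "split_failed", split_cohort, cohort, split)
    manifest["counts"]["estimation_women"] = est.n_women
    manifest["counts"]["validation_women"] = val.n_women

    stacked = _stage("stack", "stack_failed", build_stacked, est)
    manifest["counts"]["stacked_records"] = len(stacked)
    manifest["counts"]["stacked_events"] = int(
        stacked.groupby("woman_id")["event"].first().sum()
    )
    if config.export_stacked:
        stacked.to_csv(out / "stacked.csv", index=False)

    log.info("fitting partly conditional Cox on %d records", len(stacked))
    fit = _stage("fit", "fit_failed", fit_pc_cox, stacked, CovariateSpec())
    fit.to_json(out / "fit.json")
    pd.DataFrame(
        {"time": fit.baseline_times, "cum_hazard": fit.baseline_cumhaz}
    ).to_csv(out / "baseline_hazard.csv", index=False)
    table2 = hazard_ratio_table(fit, stacked)
    table2.to_csv(out / "table2.csv", index=False)

    log.info("validating on %d held-out women", val.n_women)
    report = _stage(
        "validate",
        "validation_failed",
        validate_model,
        fit,
        val,
        config.horizons,
        config.subgroup_tau,
        smr_method=config.smr_method,
    )
    report["per_horizon"].to_csv(out / "table3.csv", index=False)
    pd.DataFrame([dataclasses.asdict(c) for c in report["subgroups"]]).to_csv(
        out / "table4.csv", index=False
    )
    fig1 = []
    for tau, bins in report["risk_bins"].items():
        b = bins.copy()
        b.insert(0, "horizon", tau)
        fig1.append(b)
    if fig1:
        pd.concat(fig1, ignore_index=True).to_csv(out / "fig1_bins.csv", index=False)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    log.info("run complete: %s", out)
    return out


def run_from_manifest(manifest_path) -> Path:
    """Re-execute a run from its manifest (bitwise-reproducible outputs)."""
    with open(manifest_path) as fh:
        m = json.load(fh)
    cfg_d = dict(m["config"])
    sim_d = cfg_d.pop("simulation", None)
    cfg_d = {k: v for k, v in cfg_d.items() if k in {f.name for f in dataclasses.fields(RunConfig)}}
    cfg = RunConfig(**cfg_d)
    if sim_d is not None:
        sim_d.pop("seed", None)
        cfg.simulation = SimulationConfig.from_dict({**sim_d, "seed": 0})
    cfg.seed = m["seed"]
    return run_pipeline(cfg)
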