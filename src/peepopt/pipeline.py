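"""End-to-end orchestration: simulate -> load -> fit -> recommend -> report.

A single YAML config drives every stage; given the same config and seed the
report bundle is byte-identical (no timestamps are written).  Artifacts:
the waveform (when simulated), extracted loops, the trial-fit JSON with its
per-PEEP table, the PEEP recommendation, a compliance summary, and a QC
report listing auto-PEEP, resistance, anomaly flags and excluded levels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import (compliance_analysis, decision_metrics, recruitment_model,
               synthetic_data, waveform_io)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "track_fits"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and cause."""

    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


_SECTIONS = {
    "simulate": {"enabled", "truth", "script"},
    "input": {"waveform", "loops", "columns", "holds", "set_peep",
              "auto_peep", "resistance", "baseline_ml"},
    "fit": {"sd_min", "sd_max", "tlc_min", "tlc_max", "objective",
            "offset", "correct_resistance"},
    "metrics": {"tolerance"},
    "compliance": {"max_ratio", "reference_tlc_ml"},
}
_TOP_LEVEL = set(_SECTIONS) | {"output_dir", "seed", "trial_id"}


@dataclass
class RunConfig:
    """Validated pipeline configuration (one YAML document)."""

    output_dir: Path
    seed: int = 0
    trial_id: str = "trial"
    simulate: dict = field(default_factory=dict)
    input: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    compliance: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _TOP_LEVEL
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "output_dir" not in data:
            raise ValueError("config requires 'output_dir'")
        for section, allowed in _SECTIONS.items():
            sub = data.get(section, {})
            if not isinstance(sub, dict):
                raise ValueError(f"config section '{section}' must be a map")
            bad = set(sub) - allowed
            if bad:
                raise ValueError(
                    f"unknown keys in config section '{section}': "
                    f"{sorted(bad)}")
        seed = data.get("seed", 0)
        if not isinstance(seed, int):
            raise ValueError("seed must be an integer")
        return cls(output_dir=Path(data["output_dir"]), seed=seed,
                   trial_id=str(data.get("trial_id", "trial")),
                   simulate=data.get("simulate", {}),
                   input=data.get("input", {}),
                   fit=data.get("fit", {}),
                   metrics=data.get("metrics", {}),
                   compliance=data.get("compliance", {}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError("config file must contain a YAML mapping")
        return cls.from_dict(data)

    def resolved(self) -> dict:
        """Every effective setting, defaults included, for provenance."""
        out = dataclasses.asdict(self)
        out["output_dir"] = str(self.output_dir)
        out["fit_defaults"] = dataclasses.asdict(
            recruitment_model.FitConfig())
        out["io_defaults"] = dataclasses.asdict(waveform_io.IoConfig())
        return out


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return inner
    return wrap


@_stage("simulate")
def _simulate(config: RunConfig, out: Path):
    truth_kwargs = dict(config.simulate.get("truth", {}))
    truth_kwargs.setdefault("seed", config.seed)
    truth = synthetic_data.GroundTruth(**truth_kwargs)
    script = synthetic_data.ProtocolScript(
        **config.simulate.get("script", {}))
    man = synthetic_data.generate_manoeuvre(truth, script)
    waveform_io.write_waveform_csv(man.record, out / "waveform.csv")
    synthetic_data.write_ground_truth_json(man, out / "ground_truth.json")
    return man


@_stage("load")
def _load(config: RunConfig, out: Path, man):
    io_cfg = waveform_io.IoConfig(**config.input.get("columns", {})) \
        if config.input.get("columns") else waveform_io.DEFAULT_CONFIG
    if man is not None:
        record = man.record
        holds = man.hold_windows
        set_peep = float(man.set_peep_levels[0])
    elif config.input.get("waveform"):
        path = Path(config.input["waveform"])
        if not path.exists():
            raise FileNotFoundError(
                f"input waveform not found: {path} (and simulate is off)")
        record = waveform_io.load_waveform(path, io_cfg)
        holds = config.input.get("holds") or {}
        set_peep = float(config.input.get("set_peep", 0.0))
    else:
        raise FileNotFoundError(
            "no input: set input.waveform or enable simulate")
    return record, holds, set_peep, io_cfg


@_stage("holds")
def _holds(config, record, holds, set_peep):
    auto_peep = config.input.get("auto_peep")
    resistance = config.input.get("resistance")
    peak = plateau = 0.0
    if auto_peep is None and "end_exp" in holds:
        auto_peep = waveform_io.estimate_auto_peep(
            record, tuple(holds["end_exp"]), set_peep=set_peep)
    if resistance is None and "end_insp" in holds:
        resistance = waveform_io.estimate_resistance(
            record, tuple(holds["end_insp"]))
    return (0.0 if auto_peep is None else float(auto_peep),
            resistance)


@_stage("extract")
def _extract(config, record, io_cfg, out: Path):
    segments = waveform_io.segment_breaths(record, config=io_cfg)
    if not segments:
        raise ValueError("no breaths detected")
    flags = waveform_io.flag_pressure_drop_anomaly(record, segments, io_cfg)
    baseline = float(config.input.get("baseline_ml", 0.0))
    loops = waveform_io.extract_pv_loops(record, segments, config=io_cfg,
                                         baseline_ml=baseline)
    waveform_io.write_loops_csv(loops, out / "loops.csv")
    return segments, loops, flags


@_stage("fit")
def _fit(config: RunConfig, loops, auto_peep, resistance, out: Path):
    fit_kwargs = {k: v for k, v in config.fit.items()
                  if k != "correct_resistance"}
    fit_cfg = recruitment_model.FitConfig(**fit_kwargs) if fit_kwargs \
        else recruitment_model.DEFAULT_FIT
    if resistance and config.fit.get("correct_resistance", True):
        loops = [waveform_io.correct_resistive_pressure(l, resistance)
                 for l in loops]
    trial = recruitment_model.fit_trial(loops, auto_peep, fit_cfg,
                                        trial_id=config.trial_id)
    trial.save_json(out / "trial_fit.json")
    trial.to_table().to_csv(out / "fit_table.csv", float_format="%.2f")
    return trial


@_stage("recommend")
def _recommend(config: RunConfig, trial, out: Path):
    kwargs = {}
    if "tolerance" in config.metrics:
        kwargs["tolerance"] = float(config.metrics["tolerance"])
    rec = decision_metrics.recommend(trial, **kwargs)
    rec.save_json(out / "recommendation.json")
    row = pd.DataFrame([{
        "trial": trial.trial_id,
        "auto_peep_cmh2o": trial.auto_peep,
        "inflation_sd": trial.inflation_sd,
        "top_peep": rec.top_peep,
        "tcp_peep": rec.tcp_peep,
        "net_recruitment_peep": rec.net_recruitment_peep,
        "class": rec.recruitability_class,
    }])
    row.to_csv(out / "selection_summary.csv", index=False,
               float_format="%.1f")
    return rec


@_stage("compliance")
def _compliance(config: RunConfig, loops, trial, out: Path):
    if len(loops) < 3:
        return None
    summary = compliance_analysis.summarise_compliance(
        loops, trial.tlc_ml,
        max_ratio=float(config.compliance.get("max_ratio", 1.5)),
        reference_tlc_ml=float(
            config.compliance.get("reference_tlc_ml", 1000.0)))
    pd.DataFrame([{
        "linear_peep_low": summary.linear_peep_range[0],
        "linear_peep_high": summary.linear_peep_range[1],
        "linear_compliance_min": summary.linear_compliance_range[0],
        "linear_compliance_max": summary.linear_compliance_range[1],
        "highest_peep": summary.highest_peep,
        "compliance_at_max_peep": summary.compliance_at_max_peep,
        "linear_compliance": summary.linear_compliance,
        "tlc_ml": summary.tlc_ml,
        "normalised_compliance": summary.normalised_compliance,
    }]).to_csv(out / "compliance_summary.csv", index=False,
               float_format="%.2f")
    return summary


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every configured stage; returns the in-memory artifacts.

    Deterministic for a fixed config and seed.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_resolved.json").write_text(
        json.dumps(config.resolved(), indent=2, sort_keys=True, default=str))

    man = None
    if config.simulate.get("enabled", False):
        man = _simulate(config, out)
    record, holds, set_peep, io_cfg = _load(config, out, man)
    auto_peep, resistance = _holds(config, record, holds, set_peep)
    segments, loops, flags = _extract(config, record, io_cfg, out)
    excluded = [l.peep for l in loops if l.peep < auto_peep]
    trial = _fit(config, [l for l in loops], auto_peep, resistance, out)
    rec = _recommend(config, trial, out)
    summary = _compliance(config, loops, trial, out)
    qc = {
        "auto_peep_cmh2o": auto_peep,
        "inspiratory_resistance_cmh2o_s_per_l":
            None if resistance is None else float(resistance),
        "pressure_drop_anomaly_breaths": sorted(int(i) for i in flags),
        "excluded_peep_levels": sorted(float(p) for p in excluded),
    }
    (out / "qc.json").write_text(json.dumps(qc, indent=2, sort_keys=True))
    return {"record": record, "loops": loops, "trial_fit": trial,
            "recommendation": rec, "compliance": summary,
            "anomaly_flags": flags, "excluded_peeps": excluded,
            "auto_peep": auto_peep, "resistance": resistance,
            "manoeuvre": man}


def track_fits(fit_paths: list[str | Path], out_path: str | Path | None = None
               ) -> decision_metrics.DiseaseTrajectory:
    """Load a time-ordered list of trial-fit JSONs and build the disease
    trajectory."""
    series = []
    for p in fit_paths:
        fit = recruitment_model.TrialFit.load_json(p)
        series.append((fit.trial_id, fit))
    traj = decision_metrics.build_trajectory(series)
    if out_path is not None:
        Path(out_path).write_text(
            json.dumps(traj.to_dict(), indent=2, sort_keys=True))
    return traj
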