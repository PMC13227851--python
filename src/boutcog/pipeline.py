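"""End-to-end orchestration: simulate/extract -> indices -> align -> fit -> power.

Driven by one YAML/dict configuration; every stage writes its table to the
output directory and the run ends with a manifest JSON recording the seed,
config hash, per-stage row counts, exclusion percentages and the six model
summaries (two outcomes x three bout classes).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bouts as bx
from . import cognition as cg
from . import indices as ix
from . import qc
from .functional import ModelSpec, fit_model
from .power import PowerConfig, power_table, simulate_power
from .simulate import SimConfig, generate_cohort, write_cohort

__all__ = ["default_config", "validate_config", "run_pipeline"]

DEFAULT_MODELS = [
    {"outcome": "median_rt", "bout_class": "MVPA"},
    {"outcome": "median_rt", "bout_class": "LPA"},
    {"outcome": "median_rt", "bout_class": "SED"},
    {"outcome": "mean_correct", "bout_class": "MVPA"},
    {"outcome": "mean_correct", "bout_class": "LPA"},
    {"outcome": "mean_correct", "bout_class": "SED"},
]

KNOWN_KEYS = {
    "seed", "out_dir", "simulate", "events", "trials", "demographics",
    "wake_start", "wake_end", "wear_hours_min", "sessions_min",
    "dow_aggregation", "rt_mode", "models", "power", "run_power", "log_level",
}


def default_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "simulate": {"n_subjects": 25, "n_days": 14, "low_wear_prob": 0.04},
        "wake_start": 6.0,
        "wake_end": 22.0,
        "wear_hours_min": 10.0,
        "sessions_min": 1,
        "dow_aggregation": "pool",
        "rt_mode": "pooled",
        "models": DEFAULT_MODELS,
        "run_power": False,
        "power": {"n_sims": 200, "icc_grid": [0.3, 0.6], "beta_grid": [0.0, 0.05, 0.1]},
    }


def validate_config(config: dict) -> dict:
    """Schema check; returns {'errors': [...], 'warnings': [...]}.

    Unknown top-level keys warn; missing or malformed required keys error
    with their path so nothing runs on an invalid config.
    """
    errors, warns = [], []
    for key in config:
        if key not in KNOWN_KEYS:
            warns.append(f"unknown key {key!r} ignored")
    for key in ("wear_hours_min", "sessions_min"):
        if key not in config:
            errors.append(f"missing required key {key!r}")
        elif not isinstance(config[key], (int, float)) or config[key] <= 0:
            errors.append(f"{key} must be a positive number, got {config[key]!r}")
    if "simulate" not in config and not all(
        k in config for k in ("events", "trials", "demographics")
    ):
        errors.append("need either a 'simulate' block or events/trials/demographics paths")
    if config.get("dow_aggregation", "pool") not in ("pool", "per_day_mean"):
        errors.append(f"dow_aggregation: unknown mode {config.get('dow_aggregation')!r}")
    models = config.get("models", DEFAULT_MODELS)
    if not isinstance(models, list) or not models:
        errors.append("models must be a non-empty list")
    else:
        for i, m in enumerate(models):
            try:
                ModelSpec(**m)
            except (TypeError, ValueError) as exc:
                errors.append(f"models[{i}]: {exc}")
    return {"errors": errors, "warnings": warns}


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Run every stage and return (and write) the manifest."""
    report = validate_config(config)
    if report["errors"]:
        raise ValueError("invalid config: " + "; ".join(report["errors"]))
    out = Path(out_dir or config.get("out_dir", "boutcog_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    wake = (float(config["wake_start"]), float(config["wake_end"]))
    manifest: dict = {
        "config_hash": _hash_obj(config),
        "seed": seed,
        "stages": {},
        "warnings": report["warnings"],
    }

    # --- stage: input tables (simulated or read from disk)
    if "simulate" in config:
        sim_cfg = SimConfig(**{**config["simulate"], "seed": seed})
        cohort = generate_cohort(sim_cfg)
        write_cohort(cohort, out)
        events, trials, demo = cohort.events, cohort.trials, cohort.demographics
    else:
        events = bx.read_events(config["events"])
        trials = cg.read_trials(config["trials"])
        demo = pd.read_csv(config["demographics"])
    manifest["stages"]["input"] = {
        "n_events": len(events),
        "n_trials": len(trials),
        "n_subjects": len(demo),
    }

    # --- stage: bout extraction + day summaries
    bout_frames, summary_rows = [], []
    for sid, ev in events.groupby("subject_id", sort=True):
        b = bx.extract_bouts(ev)
        bout_frames.append(b)
        for date in sorted(pd.to_datetime(ev["start"]).dt.date.unique()):
            day_ev = ev[pd.to_datetime(ev["start"]).dt.date == date]
            summary_rows.append(bx.summarize_day(b, day_ev, date, wake))
    bouts = pd.concat(bout_frames, ignore_index=True)
    summaries = pd.DataFrame(summary_rows)
    bouts_out = bouts.copy()
    bouts_out["start"] = pd.to_datetime(bouts_out["start"]).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    bouts_out.to_csv(out / "bouts.csv", index=False, float_format="%.10g")
    summaries.to_csv(out / "day_summary.csv", index=False, float_format="%.10g")
    manifest["stages"]["bouts"] = {"n_bouts": len(bouts), "n_days": len(summaries)}

    # --- stage: cognition
    cogdays = cg.aggregate_days(trials, rt_mode=config.get("rt_mode", "pooled"))
    cogdays.to_csv(out / "cogdays.csv", index=False, float_format="%.10g")
    manifest["stages"]["cognition"] = {"n_days": len(cogdays)}

    # --- stage: QC
    valid = qc.flag_valid_days(
        summaries, cogdays,
        wear_hours_min=float(config["wear_hours_min"]),
        sessions_min=int(config["sessions_min"]),
    )
    valid.to_csv(out / "valid_days.csv", index=False, float_format="%.10g")
    excl = qc.exclusion_report(valid)
    with open(out / "exclusions.json", "w") as fh:
        json.dump(excl, fh, indent=1)
    manifest["stages"]["qc"] = {
        "n_days": len(valid),
        "pct_excluded": round(excl["pct_excluded"], 3),
    }

    # --- stage: indices
    vd = valid[valid["valid"]][["subject_id", "date", "dow"]]
    idx = ix.dow_indices(bouts, vd, aggregation=config.get("dow_aggregation", "pool"))
    ix.index_report(idx).to_csv(out / "indices.csv", index=False, float_format="%.10g")
    manifest["stages"]["indices"] = {"n_rows": len(idx)}

    # --- stage: analysis table
    table = qc.build_analysis_table(valid, cogdays, idx, demo)
    table.to_csv(out / "analysis.csv", index=False, float_format="%.10g")
    manifest["stages"]["align"] = {"n_rows": len(table)}

    # --- stage: the six models
    fits = {}
    for m in config.get("models", DEFAULT_MODELS):
        spec = ModelSpec(**m)
        key = f"{spec.outcome}_{spec.bout_class}"
        result = fit_model(table, spec)
        fits[key] = result.to_dict()
        result.curves_frame().to_csv(out / f"curves_{key}.csv", index=False, float_format="%.6g")
        with open(out / f"fit_{key}.json", "w") as fh:
            json.dump(result.to_dict(), fh, indent=1)
    manifest["stages"]["fit"] = {
        key: {
            "adjusted_r2": f["adjusted_r2"],
            "gini_wald_p": f["curves"]["gini"]["wald_p"],
            "n_obs": f["n_obs"],
        }
        for key, f in fits.items()
    }

    # --- stage: power (optional)
    if config.get("run_power"):
        pcfg = PowerConfig(**{**config.get("power", {}), "seed": seed})
        pres = simulate_power(pcfg)
        pres.table.to_csv(out / "power.csv", index=False, float_format="%.6g")
        power_table(pres).to_csv(out / "power_table.csv", float_format="%.3f")
        manifest["stages"]["power"] = {"n_cells": len(pres.table)}

    manifest["outputs"] = {
        p.name: _hash_file(p) for p in sorted(out.glob("*.csv")) if p.is_file()
    }
    manifest["manifest_hash"] = _hash_obj(
        {k: manifest[k] for k in ("config_hash", "seed", "stages", "outputs")}
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
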