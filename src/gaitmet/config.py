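"""Run configuration and the end-to-end synthetic pipeline.

The configuration is a single YAML document with a strict schema (unknown
keys are rejected).  ``run_pipeline`` chains the stages — synthesize (or
load) a trial, optionally calibrate passive parameters, solve the
redundancy problem, evaluate the requested metabolic models, and aggregate —
writing CSV/storage artifacts stamped with the package version and a config
hash so a rerun with the same seed is reproducible bit-for-bit.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .aggregation import BASAL_RATE, energy_report
from .metabolics import MODEL_IDS, compute_metabolic_rates
from .redundancy import SolverOptions, solve_redundancy
from .synth import (
    MUSCLE_GROUP_MAP,
    TENDON_GROUPS,
    make_gait_trial,
    make_virtual_subject,
)

__all__ = ["RunConfig", "load_config", "run_pipeline"]

_SCHEMA = {
    "workflow": str,
    "seed": int,
    "speed": float,
    "models": list,
    "basal_rate": float,
    "n_mesh": int,
    "out_dir": str,
    "subject_seed": int,
    "trial_mode": str,
    "emg_channels": list,
    "zero_metabolic_override": bool,
}

_DEFAULTS = {
    "workflow": "GEN",
    "seed": 1,
    "speed": 1.25,
    "models": list(MODEL_IDS),
    "basal_rate": BASAL_RATE,
    "n_mesh": 30,
    "out_dir": "gaitmet_out",
    "subject_seed": 1,
    "trial_mode": "open_loop",
    "emg_channels": [],
    "zero_metabolic_override": False,
}


@dataclass
class RunConfig:
    values: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.values) - set(_SCHEMA)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(_DEFAULTS)
        merged.update(self.values)
        for k, v in merged.items():
            want = _SCHEMA[k]
            if want is float and isinstance(v, int):
                v = float(v)
            if not isinstance(v, want):
                raise TypeError(f"config key {k!r} must be {want.__name__}")
            merged[k] = v
        if merged["workflow"] not in ("GEN", "PAS", "TEN", "EMG"):
            raise ValueError(f"unknown workflow {merged['workflow']!r}")
        for m in merged["models"]:
            if m not in MODEL_IDS:
                raise ValueError(f"unknown metabolic model {m!r}")
        if merged["workflow"] == "EMG" and not merged["emg_channels"]:
            raise ValueError("EMG workflow requires emg_channels")
        self.values = merged

    def __getitem__(self, k):
        return self.values[k]

    @property
    def hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        vals = {k: v for k, v in self.values.items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(vals, sort_keys=True).encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return RunConfig(doc)


def run_pipeline(config: RunConfig):
    """Execute the configured pipeline; returns {model: EnergyReport} and
    writes artifacts under ``out_dir``."""
    cfg = config
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stamp = [f"gaitmet {__version__}", f"config {cfg.hash}",
             f"seed {cfg['seed']}"]

    subject = make_virtual_subject(cfg["subject_seed"])
    trial = make_gait_trial(subject, cfg["speed"], cfg["seed"],
                            mode=cfg["trial_mode"],
                            n_time=10 * cfg["n_mesh"] + 1)
    opts = SolverOptions(n_mesh=cfg["n_mesh"])
    emg_map = None
    tendon_groups = None
    if cfg["workflow"] == "EMG":
        from .synth import make_emg_envelopes
        make_emg_envelopes(trial, cfg["emg_channels"], cfg["seed"])
        emg_map = {c: c for c in cfg["emg_channels"]}
        tendon_groups = TENDON_GROUPS
    elif cfg["workflow"] == "TEN":
        tendon_groups = TENDON_GROUPS
    sol = solve_redundancy(trial, subject.muscles, cfg["workflow"],
                           emg_map=emg_map, tendon_groups=tendon_groups,
                           opts=opts)

    spanned = {p.name: p.joints_spanned for p in subject.muscles}
    reports = {}
    rows = []
    for model in cfg["models"]:
        traj = compute_metabolic_rates(model, sol, subject.muscles)
        edot = traj.edot
        if cfg["zero_metabolic_override"]:
            edot = np.zeros_like(edot)
        rep = energy_report(
            edot, traj.time, sol.trial.arms, traj.muscle_names,
            sol.trial.dofs, spanned, MUSCLE_GROUP_MAP, sol.trial.events,
            subject.mass, basal=cfg["basal_rate"], model=model,
            workflow=cfg["workflow"], speed=cfg["speed"])
        reports[model] = rep
        rows.append({
            "model": model, "workflow": cfg["workflow"], "speed": cfg["speed"],
            "whole_body_rate_W_per_kg": rep.whole_body_rate,
            "stance_share_pct": rep.stance_share,
            "swing_share_pct": rep.swing_share,
            **{f"share_{g.replace(' ', '_')}_pct": s
               for g, s in sorted(rep.group_shares.items())},
        })

    import pandas as pd

    df = pd.DataFrame(rows)
    report_path = out / "energy_report.csv"
    with open(report_path, "w") as fh:
        for s in stamp:
            fh.write(f"# {s}\n")
        df.to_csv(fh, index=False, float_format="%.10g")
    return reports
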