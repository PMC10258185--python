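"""Serialization and the end-to-end run pipeline.

Time series go to CSV (SI units), run metadata and summaries to JSON.  Every
pipeline run echoes a configuration record (with a content hash, seeds and
library versions) sufficient to reproduce it exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ConflictTrace, MotionStimulus, PerceptionTrace
from .sickness import SicknessWeights, ms_integrate

_STIM_COLUMNS = ["t", "fx", "fy", "fz", "wx", "wy", "wz"]


def stimulus_to_csv(stim: MotionStimulus, path: str | Path) -> Path:
    """Write a stimulus to CSV plus a JSON sidecar with paradigm metadata."""
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack([stim.t, stim.f_h.T, stim.omega_h.T]), columns=_STIM_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"paradigm": stim.paradigm, "params": stim.params}, sort_keys=True)
    )
    return path


def stimulus_from_csv(path: str | Path) -> MotionStimulus:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {"paradigm": "custom", "params": {}}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return MotionStimulus(
        t=df["t"].to_numpy(),
        f_h=df[["fx", "fy", "fz"]].to_numpy().T,
        omega_h=df[["wx", "wy", "wz"]].to_numpy().T,
        paradigm=meta["paradigm"],
        params=meta["params"],
    )


def traces_to_csv(
    percept: PerceptionTrace, conflicts: ConflictTrace, path: str | Path
) -> Path:
    """Write perception and conflict traces to one wide CSV."""
    path = Path(path)
    cols = {"t": percept.t}
    for name, series in (
        ("g_hat", percept.g_hat),
        ("a_hat", percept.a_hat),
        ("v_hat", percept.v_hat),
        ("w_hat", percept.w_hat),
    ):
        for i, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = series[i]
    for i, ax in enumerate("wxyz"):
        cols[f"theta_hat_{ax}"] = percept.theta_hat[i]
    for key, series in conflicts.conflicts.items():
        for i, ax in enumerate("xyz"):
            cols[f"{key}_{ax}"] = series[i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    return path


@dataclass
class RunConfig:
    """One end-to-end run: stimulus -> model -> conflicts -> sickness."""

    model: str = "svm"
    preset: str | None = "perception"
    params: dict = field(default_factory=dict)   # explicit overrides
    paradigm: str = "EVAR"
    paradigm_params: dict = field(default_factory=dict)
    duration: float = 200.0
    dt: float = 0.01
    seeds: list[int] = field(default_factory=lambda: [0])
    metric: str = "ms"  # "ms" or "msi"

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute a run configuration and return (and optionally write) the
    summary.  Deterministic given the seeds in the config."""
    from . import __version__
    from .analysis import fit_time_constant, resolve_params, simulate_model
    from .stimuli import make_paradigm

    if cfg.model.lower() not in ("svm", "msom", "pfm"):
        raise ValueError(f"config error: unknown model {cfg.model!r}")
    params = resolve_params(cfg.model, cfg.preset or "perception")
    if cfg.params:
        from dataclasses import replace

        try:
            params = replace(params, **cfg.params)
        except TypeError as exc:
            raise ValueError(f"config error in 'params': {exc}") from exc

    stim = make_paradigm(
        cfg.paradigm, duration=cfg.duration, dt=cfg.dt, **cfg.paradigm_params
    )
    weights = SicknessWeights.preset(cfg.model.lower())

    seeds = cfg.seeds if cfg.model.lower() == "pfm" else [None]
    ms_values = []
    percept = conflicts = None
    for seed in seeds:
        percept, conflicts = simulate_model(cfg.model, params, stim, seed=seed)
        ms_values.append(ms_integrate(conflicts, weights).ms_final)

    summary: dict = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "versions": {"vsom": __version__, "numpy": np.__version__},
        "ms_final": float(np.mean(ms_values)),
        "ms_per_seed": [float(v) for v in ms_values],
        "conflict_types": sorted(conflicts.keys()),
    }
    if cfg.paradigm.upper() == "EVAR":
        try:
            fit = fit_time_constant(
                stim.t,
                percept.yaw_velocity_percept(),
                form="decay",
                window=(3.0, min(100.0, cfg.duration)),
            )
            summary["evar_yaw_time_constant_s"] = 1.0 / fit.b
        except (RuntimeError, ValueError):
            summary["evar_yaw_time_constant_s"] = None

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stimulus_to_csv(stim, out_dir / "stimulus.csv")
        traces_to_csv(percept, conflicts, out_dir / "traces.csv")
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
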