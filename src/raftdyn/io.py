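"""CSV/JSON/YAML readers and writers for the package's data objects.

Measured data enter as plain CSV: ACF curves as (lag_s, g[, g_err]),
FRAP curves as (time_s, intensity), per-waist diffusion times as
(waist_um, tau_d_ms[, tau_d_sem_ms, n_cells]).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diffusion_law import DiffusionLaw, WaistMeasurement
from .errors import ConfigError
from .fcs import ACFCurve
from .frap import FRAPCurve
from .sim import SimulationConfig, TrajectoryEnsemble


def write_trajectory_csv(ensemble: TrajectoryEnsemble, path) -> None:
    """Long-format trajectory export: particle_id, frame, x_um, y_um, in_domain."""
    n_p, n_f = ensemble.n_particles, ensemble.n_frames
    df = pd.DataFrame({
        "particle_id": np.repeat(np.arange(n_p), n_f),
        "frame": np.tile(np.arange(n_f), n_p),
        "x_um": ensemble.positions[:, :, 0].ravel(),
        "y_um": ensemble.positions[:, :, 1].ravel(),
        "in_domain": ensemble.in_domain.ravel().astype(int),
    })
    df.to_csv(path, index=False)


def write_trajectory_npz(ensemble: TrajectoryEnsemble, path) -> None:
    """Compact binary export of an ensemble."""
    np.savez_compressed(path, positions=ensemble.positions,
                        in_domain=ensemble.in_domain,
                        dt=ensemble.dt, box_size=ensemble.box_size)


def read_trajectory_npz(path) -> TrajectoryEnsemble:
    with np.load(path) as z:
        return TrajectoryEnsemble(positions=z["positions"],
                                  in_domain=z["in_domain"],
                                  dt=float(z["dt"]),
                                  box_size=float(z["box_size"]))


def save_sim_config(config: SimulationConfig, path) -> None:
    path = Path(path)
    doc = dataclasses.asdict(config)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc))
    else:
        path.write_text(json.dumps(doc, indent=2))


def load_sim_config(path) -> SimulationConfig:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return SimulationConfig(**doc)


def write_acf_csv(curve: ACFCurve, path) -> None:
    df = pd.DataFrame({"lag_s": curve.lags, "g": curve.g})
    if curve.g_err is not None:
        df["g_err"] = curve.g_err
    df.to_csv(path, index=False)


def read_acf_csv(path) -> ACFCurve:
    df = pd.read_csv(path)
    for col in ("lag_s", "g"):
        if col not in df.columns:
            raise ConfigError(f"ACF CSV must have a {col!r} column")
    err = df["g_err"].to_numpy(float) if "g_err" in df.columns else None
    return ACFCurve(lags=df["lag_s"].to_numpy(float),
                    g=df["g"].to_numpy(float), g_err=err)


def read_law_points_csv(path) -> list[WaistMeasurement]:
    """Per-waist diffusion times from a tidy CSV (waist_um, tau_d_ms, ...)."""
    df = pd.read_csv(path)
    for col in ("waist_um", "tau_d_ms"):
        if col not in df.columns:
            raise ConfigError(f"law CSV must have a {col!r} column")
    df = df.dropna(subset=["waist_um", "tau_d_ms"])
    points = []
    def _num(row, col, default):
        v = row.get(col, default)
        try:
            v = float(v)
        except (TypeError, ValueError):
            return default
        return default if np.isnan(v) else v

    for _, row in df.iterrows():
        points.append(WaistMeasurement(
            waist_sq=float(row["waist_um"]) ** 2,
            tau_d_mean=float(row["tau_d_ms"]),
            tau_d_sem=_num(row, "tau_d_sem_ms", 0.0),
            n_cells=int(_num(row, "n_cells", 1))))
    return points


def write_law_csv(condition: str, law: DiffusionLaw, path) -> None:
    """Tidy per-waist table plus one summary row mirroring the svFCS layout."""
    rows = [{"condition": condition, "row": "waist",
             "waist_um": float(np.sqrt(p.waist_sq)),
             "waist_sq_um2": p.waist_sq, "tau_d_ms": p.tau_d_mean,
             "tau_d_sem_ms": p.tau_d_sem, "n_cells": p.n_cells}
            for p in law.points]
    rows.append({"condition": condition, "row": "summary",
                 "t0_ms": law.t0, "t0_sem_ms": law.t0_sem,
                 "d_eff_um2_s": law.d_eff, "d_eff_sem_um2_s": law.d_eff_sem,
                 "regime": law.regime})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_frap_csv(curve: FRAPCurve, path) -> None:
    df = pd.DataFrame({"time_s": curve.times, "intensity": curve.intensity})
    if curve.normalized is not None:
        df["normalized"] = curve.normalized
    df.to_csv(path, index=False)


def read_frap_csv(path) -> FRAPCurve:
    df = pd.read_csv(path)
    for col in ("time_s", "intensity"):
        if col not in df.columns:
            raise ConfigError(f"FRAP CSV must have a {col!r} column")
    norm = df["normalized"].to_numpy(float) if "normalized" in df.columns else None
    return FRAPCurve(times=df["time_s"].to_numpy(float),
                     intensity=df["intensity"].to_numpy(float),
                     normalized=norm)
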