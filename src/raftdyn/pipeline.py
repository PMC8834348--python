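"""End-to-end virtual experiments per condition.

Two fidelity tiers share the same inference code path:

* ``law_level`` — draws per-cell diffusion times directly from a condition's
  ground-truth diffusion-law line (seconds-fast; used for round-trip and
  calibration studies), then fits the law.
* ``particle`` — runs the microscopic Monte Carlo: per cell, trajectories
  are simulated and observed through Gaussian spots of each waist for a
  series of runs; run-averaged ACFs are fitted per cell, τd aggregated per
  waist, and the diffusion law fitted (minutes-scale).

All randomness derives from a single root seed through
``numpy.random.SeedSequence`` child streams, recorded in the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import presets
from .acf_fit import fit_acf
from .diffusion_law import (DiffusionLaw, aggregate_cells, fit_diffusion_law,
                            generate_law_points)
from .errors import ConfigError
from .fcs import DetectionProfile, average_runs, intensity_trace, multitau_acf
from .frap import FRAPConfig, disk_half_time_factor, fit_frap, normalize_frap, simulate_frap
from .sim import init_domains, simulate

__all__ = [
    "ExperimentSpec", "ConditionReport", "FrapSummary",
    "run_svfcs_experiment", "run_frap_experiment", "compare_conditions",
    "DEFAULT_WAISTS",
]

logger = logging.getLogger("raftdyn")

#: default spot waists (µm): four sizes spanning the diffraction-limited
#: range of 488 nm illumination
DEFAULT_WAISTS = (0.20, 0.25, 0.30, 0.35)


@dataclass(frozen=True)
class ExperimentSpec:
    """Specification of one svFCS virtual experiment."""

    condition: str
    waists: tuple[float, ...] = DEFAULT_WAISTS
    n_cells: int = 15
    runs_per_cell: int = 20
    run_duration: float = 5.0
    seed: int = 0
    mode: str = "law_level"          # "law_level" | "particle"
    cell_noise_cv: float = 0.15      # law_level only
    n_particles: int | None = None   # particle only; None = preset default
    bin_time: float | None = None    # particle only; None = preset dt
    allow_any_n_cells: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("law_level", "particle"):
            raise ConfigError("mode must be 'law_level' or 'particle'")
        if len(self.waists) < 2:
            raise ConfigError("need >= 2 waists")
        if self.runs_per_cell < 1:
            raise ConfigError("runs_per_cell must be >= 1")
        if not self.allow_any_n_cells and not (10 <= self.n_cells <= 20):
            raise ConfigError(
                "n_cells outside the conventional 10-20 range; set "
                "allow_any_n_cells=True to override")


@dataclass
class ConditionReport:
    """Table-1-style summary for one condition, with full provenance."""

    condition: str
    mode: str
    law: DiffusionLaw
    provenance: dict = field(default_factory=dict)

    def per_waist_table(self) -> pd.DataFrame:
        rows = [{"condition": self.condition,
                 "waist_um": float(np.sqrt(p.waist_sq)),
                 "waist_sq_um2": p.waist_sq,
                 "tau_d_ms": p.tau_d_mean,
                 "tau_d_sem_ms": p.tau_d_sem,
                 "n_cells": p.n_cells} for p in self.law.points]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {"condition": self.condition, "mode": self.mode,
                "t0_ms": self.law.t0, "t0_sem_ms": self.law.t0_sem,
                "d_eff_um2_s": self.law.d_eff,
                "d_eff_sem_um2_s": self.law.d_eff_sem,
                "regime": self.law.regime}

    def to_json(self) -> str:
        doc = self.summary()
        doc["per_waist"] = self.per_waist_table().to_dict(orient="records")
        doc["provenance"] = self.provenance
        return json.dumps(doc, indent=2, sort_keys=True)


def _spec_hash(spec: ExperimentSpec) -> str:
    payload = json.dumps(asdict(spec), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _provenance(spec: ExperimentSpec) -> dict:
    from . import __version__
    return {"seed": spec.seed, "config_hash": _spec_hash(spec),
            "raftdyn_version": __version__,
            "spec": asdict(spec)}


def run_svfcs_experiment(spec: ExperimentSpec) -> ConditionReport:
    """Execute one svFCS experiment and fit its diffusion law."""
    logger.info("svFCS experiment: %s (%s mode, seed %d)",
                spec.condition, spec.mode, spec.seed)
    if spec.mode == "law_level":
        law_gt = presets.law_params(spec.condition)
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
        points = generate_law_points(
            law_gt.t0_ms, law_gt.d_eff, list(spec.waists),
            n_cells=spec.n_cells, cell_noise_cv=spec.cell_noise_cv, seed=rng)
    else:
        points = _particle_law_points(spec)
    law = fit_diffusion_law(points)
    logger.info("fitted law: t0 = %.3f +/- %.3f ms, D_eff = %.3f um2/s (%s)",
                law.t0, law.t0_sem, law.d_eff, law.regime)
    return ConditionReport(condition=spec.condition, mode=spec.mode, law=law,
                           provenance=_provenance(spec))


def _particle_law_points(spec: ExperimentSpec):
    """Microscopic tier: per-cell traces -> run-averaged ACF -> τd -> law."""
    config0, dspec = presets.preset(spec.condition,
                                    n_particles=spec.n_particles,
                                    duration=spec.run_duration)
    bin_time = spec.bin_time if spec.bin_time is not None else config0.dt
    root = np.random.SeedSequence(spec.seed)
    cell_seeds = root.spawn(spec.n_cells)
    brightness = 2.0
    per_waist: dict[float, list[tuple[int, float]]] = {w: [] for w in spec.waists}
    for cell_id, ss in enumerate(cell_seeds):
        rng = np.random.default_rng(ss)
        domains = init_domains(config0, dspec.area_fraction, dspec.radius,
                               rng=rng)
        state = None
        first_segment = True
        for w in spec.waists:
            curves = []
            for run in range(spec.runs_per_cell):
                # a fresh spot position per run: with nanoscopic domains only
                # a handful sit under any one spot, so re-pointing the spot
                # averages that quenched disorder the way repositioning the
                # beam between acquisitions does on a real cell
                profile = DetectionProfile(
                    waist=w, center=tuple(rng.uniform(0, config0.box_size, 2)),
                    brightness=brightness)
                ens = simulate(config0, domains, rng=rng,
                               initial_state=state,
                               burn_in=dspec.burn_in if first_segment else 0.0)
                first_segment = False
                state = ens.final_state
                trace = intensity_trace(ens, profile, bin_time, rng=rng,
                                        run_id=run, cell_id=cell_id)
                curves.append(multitau_acf(trace))
            avg = average_runs(curves)
            # two-pass fit: a wide-window pilot fit sets the final lag
            # window to ~8 tau_d.  For free diffusion this keeps the fit
            # clear of the finite-box ACF tail (which decays faster than
            # the infinite-plane model and biases tau_d down); for trapped
            # motion the slow trapping correlations inflate the pilot
            # tau_d, widening the window so the very signal behind a
            # positive intercept is not truncated
            pilot = fit_acf(avg, min_lag=3.0 * bin_time, max_lag=0.3)
            win = 8.0 * pilot.tau_d if pilot.converged else 0.3
            fit = fit_acf(avg, min_lag=3.0 * bin_time,
                          max_lag=max(win, 30.0 * bin_time))
            if not fit.converged:
                logger.warning("cell %d waist %.2f: ACF fit did not converge",
                               cell_id, w)
                continue
            per_waist[w].append((cell_id, 1000.0 * fit.tau_d))  # s -> ms
        logger.debug("cell %d done", cell_id)
    return [aggregate_cells(vals, waist=w) for w, vals in per_waist.items()]


@dataclass
class FrapSummary:
    """Across-cell summary of one FRAP condition."""

    condition: str
    n_cells: int
    t_half_mean: float
    t_half_sd: float
    mobile_fraction_mean: float   # %
    mobile_fraction_sd: float
    provenance: dict = field(default_factory=dict)


def run_frap_experiment(condition: str, n_cells: int,
                        config: FRAPConfig | None = None,
                        seed: int = 0, model: str = "disk") -> FrapSummary:
    """Simulate and quantify ``n_cells`` FRAP curves for one condition.

    The condition preset supplies the ground-truth (t₁/₂, mobile fraction);
    each virtual cell gets an independent noisy curve, each curve is
    normalized and fitted, and the summary reports mean ± SD, mirroring
    how replicate bleaching experiments are reported.
    """
    gt = presets.frap_params(condition)
    config = FRAPConfig() if config is None else config
    r = config.roi_diameter / 2.0
    tau_d = gt.t_half_s / disk_half_time_factor()
    d = r ** 2 / (4.0 * tau_d)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    t_halves, mobiles = [], []
    for _ in range(n_cells):
        raw = simulate_frap(d, gt.mobile_fraction_pct, config, rng=rng)
        fit = fit_frap(normalize_frap(raw), model=model)
        t_halves.append(fit.t_half)
        mobiles.append(fit.mobile_fraction)
    t_halves = np.asarray(t_halves)
    mobiles = np.asarray(mobiles)
    return FrapSummary(
        condition=condition, n_cells=n_cells,
        t_half_mean=float(np.nanmean(t_halves)),
        t_half_sd=float(np.nanstd(t_halves, ddof=1)) if n_cells > 1 else 0.0,
        mobile_fraction_mean=float(np.mean(mobiles)),
        mobile_fraction_sd=float(np.std(mobiles, ddof=1)) if n_cells > 1 else 0.0,
        provenance={"seed": seed, "model": model,
                    "ground_truth": asdict(gt)})


def compare_conditions(reports: list) -> pd.DataFrame:
    """Side-by-side comparison table across condition reports.

    Accepts either svFCS :class:`ConditionReport` or :class:`FrapSummary`
    objects (not mixed).  Differences and ratios are taken against the
    first report, conventionally the control.
    """
    if len(reports) < 2:
        raise ConfigError("need >= 2 reports to compare")
    kinds = {type(r) for r in reports}
    if len(kinds) > 1:
        raise ConfigError("cannot mix svFCS and FRAP reports in one table")
    rows = []
    if isinstance(reports[0], ConditionReport):
        ref = reports[0].law
        for r in reports:
            rows.append({
                "condition": r.condition,
                "t0_ms": r.law.t0, "t0_sem_ms": r.law.t0_sem,
                "d_eff_um2_s": r.law.d_eff, "d_eff_sem_um2_s": r.law.d_eff_sem,
                "regime": r.law.regime,
                "t0_diff_ms": r.law.t0 - ref.t0,
                "t0_ratio_vs_first": ref.t0 / r.law.t0 if r.law.t0 else np.inf,
                "d_eff_ratio_vs_first": ref.d_eff / r.law.d_eff,
            })
    else:
        ref = reports[0]
        for r in reports:
            rows.append({
                "condition": r.condition,
                "t_half_s": r.t_half_mean, "t_half_sd_s": r.t_half_sd,
                "mobile_fraction_pct": r.mobile_fraction_mean,
                "mobile_fraction_sd": r.mobile_fraction_sd,
                "t_half_diff_s": r.t_half_mean - ref.t_half_mean,
                "t_half_ratio_vs_first": ref.t_half_mean / r.t_half_mean,
            })
    return pd.DataFrame(rows)
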