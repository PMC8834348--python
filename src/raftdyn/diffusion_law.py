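"""The spot-variation FCS diffusion law: τd(ω²) = t₀ + ω²/(4·D_eff).

Repeating FCS at several spot sizes and regressing the mean diffusion time
on the squared waist separates the free-diffusion slope from a size-
independent offset t₀ that diagnoses sub-resolution organization: t₀ > 0
means transient trapping in nanodomains, t₀ < 0 meshwork/cytoskeleton
hindrance, t₀ ≈ 0 free Brownian diffusion.  Units follow field convention:
τd and t₀ in ms, ω in µm, D_eff in µm²/s, with the 1000x ms/s conversion
applied inside the slope→D_eff step only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import ConfigError, UnphysicalLawError

__all__ = [
    "WaistMeasurement", "DiffusionLaw",
    "aggregate_cells", "fit_diffusion_law", "classify_regime",
    "generate_law_points", "law_tau_ms",
]


@dataclass(frozen=True)
class WaistMeasurement:
    """Per-waist summary: mean and SEM of τd across cells."""

    waist_sq: float     # ω² (µm²)
    tau_d_mean: float   # ms
    tau_d_sem: float    # ms (sample SD / √n; 0 when n = 1)
    n_cells: int

    def __post_init__(self) -> None:
        if self.waist_sq <= 0:
            raise ConfigError("waist_sq must be positive")
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        if self.tau_d_sem < 0:
            raise ConfigError("tau_d_sem must be non-negative")


@dataclass(frozen=True)
class DiffusionLaw:
    """Fitted diffusion law with intercept, slope-derived D_eff and regime."""

    points: tuple[WaistMeasurement, ...]
    t0: float          # ms
    t0_sem: float      # ms
    d_eff: float       # µm²/s
    d_eff_sem: float   # µm²/s
    regime: str        # "trapped" | "meshwork" | "free"


def law_tau_ms(waist: float, t0_ms: float, d_eff: float) -> float:
    """Noise-free diffusion time (ms) at waist ω (µm) on the law line."""
    return t0_ms + 1000.0 * waist ** 2 / (4.0 * d_eff)


def aggregate_cells(per_cell_tau_d: list[tuple[object, float]], waist: float,
                    ) -> WaistMeasurement:
    """Mean ± SEM of per-cell τd (ms) at one calibrated waist (µm)."""
    if not per_cell_tau_d:
        raise ConfigError("need at least one cell")
    values = np.asarray([t for _, t in per_cell_tau_d], dtype=float)
    n = values.size
    sem = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return WaistMeasurement(waist_sq=float(waist) ** 2,
                            tau_d_mean=float(values.mean()),
                            tau_d_sem=sem, n_cells=n)


def fit_diffusion_law(points: list[WaistMeasurement],
                      regime_sigma: float = 2.0) -> DiffusionLaw:
    """Weighted linear regression of τd(ω²) across waists.

    Weights are 1/SEM² when every point has a positive SEM, else the fit is
    unweighted.  Because the weights are true standard errors of the
    per-waist means, the parameter covariance is taken at unit scale
    ("absolute sigma", (XᵀWX)⁻¹) rather than rescaled by the reduced χ²;
    an unweighted fit falls back to the usual OLS residual-scaled errors.
    D_eff = 1000/(4·slope) with slope in ms/µm²; its SEM is propagated as
    d_eff·(slope_sem/slope).  Raises :class:`UnphysicalLawError` for a
    non-positive fitted slope.
    """
    if len(points) < 2:
        raise ConfigError("need measurements at >= 2 waists")
    x = np.asarray([p.waist_sq for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise ConfigError("need >= 2 distinct waist_sq values")
    y = np.asarray([p.tau_d_mean for p in points], dtype=float)
    sems = np.asarray([p.tau_d_sem for p in points], dtype=float)
    exog = sm.add_constant(x)
    if np.all(sems > 0):
        res = sm.WLS(y, exog, weights=1.0 / sems ** 2).fit()
        t0, slope = (float(v) for v in res.params)
        t0_sem, slope_sem = (float(np.sqrt(v)) for v in
                             np.diag(res.normalized_cov_params))
    else:
        res = sm.OLS(y, exog).fit()
        t0, slope = (float(v) for v in res.params)
        with np.errstate(invalid="ignore"):  # dof = 0 on a two-point fit
            t0_sem, slope_sem = (float(v) for v in res.bse)
    if not np.isfinite(t0_sem):     # dof = 0 (two-point exact line)
        t0_sem = 0.0
    if not np.isfinite(slope_sem):
        slope_sem = 0.0
    if slope <= 0:
        raise UnphysicalLawError(
            f"fitted slope {slope:.4g} ms/µm² is non-positive; "
            "D_eff is undefined")
    d_eff = 1000.0 / (4.0 * slope)
    d_eff_sem = d_eff * slope_sem / slope
    return DiffusionLaw(points=tuple(points), t0=t0, t0_sem=t0_sem,
                        d_eff=d_eff, d_eff_sem=d_eff_sem,
                        regime=classify_regime(t0, t0_sem, regime_sigma))


def classify_regime(t0: float, t0_sem: float, sigma: float = 2.0) -> str:
    """Diffusion regime from the intercept and its uncertainty.

    "trapped" when t₀ exceeds sigma·SEM above zero (nanodomain trapping),
    "meshwork" when below −sigma·SEM (cytoskeleton-hindered), else "free".
    """
    if t0_sem < 0:
        raise ConfigError("t0_sem must be non-negative")
    if t0 > sigma * t0_sem:
        return "trapped"
    if t0 < -sigma * t0_sem:
        return "meshwork"
    return "free"


def generate_law_points(t0: float, d_eff: float, waists: list[float],
                        n_cells: int = 15, cell_noise_cv: float = 0.15,
                        seed: int | np.random.Generator | None = None,
                        ) -> list[WaistMeasurement]:
    """Law-level synthetic generator for fast round-trip experiments.

    For each waist, per-cell diffusion times are drawn from
    Normal(t₀ + 1000·ω²/(4·D_eff), (cv·mean)²) — cell-to-cell variability
    proportional to the mean — and aggregated into mean ± SEM.  The rare
    negative draw is redrawn (truncation).
    """
    if len(waists) < 2:
        raise ConfigError("need >= 2 waists")
    if n_cells < 2:
        raise ConfigError("need >= 2 cells per waist")
    if cell_noise_cv < 0:
        raise ConfigError("cell_noise_cv must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    points = []
    for w in waists:
        mu = law_tau_ms(w, t0, d_eff)
        draws = rng.normal(mu, cell_noise_cv * abs(mu), size=n_cells)
        bad = draws <= 0
        while np.any(bad):
            draws[bad] = rng.normal(mu, cell_noise_cv * abs(mu), size=bad.sum())
            bad = draws <= 0
        points.append(aggregate_cells([(i, t) for i, t in enumerate(draws)],
                                      waist=w))
    return points
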