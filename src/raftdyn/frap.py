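"""Fluorescence recovery after photobleaching for a circular ROI.

The recovery model is the closed-form solution for pure 2D diffusion into a
uniformly bleached disk (Soumpasis form),

    f(t) = e^(−2τD/t) · [ I₀(2τD/t) + I₁(2τD/t) ],      τD = r²/(4·D),

which rises from f(0)=0 to f(∞)=1; a single-exponential alternative
f(t) = 1 − e^(−t/τ) is selectable.  A measured curve is normalized by
anchoring the mean pre-bleach level to 1 and the first post-bleach frame to
0, the fit estimates the mobile fraction M ∈ [0, 1] and the recovery
timescale, and the half-time t₁/₂ is the time at which the fitted curve
reaches M/2 — for the disk model t₁/₂ ≈ 0.8946·τD (2/x*, with x* solving
e^(−x)(I₀+I₁)(x) = 1/2), for the exponential t₁/₂ = τ·ln 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import lmfit
import numpy as np
from scipy.optimize import brentq
from scipy.special import ive

from .errors import (ConfigError, DegenerateNormalizationError,
                     UnderdeterminedFitError)

__all__ = [
    "FRAPConfig", "FRAPCurve", "FRAPFit",
    "soumpasis", "simulate_frap", "normalize_frap", "fit_frap",
    "disk_half_time_factor",
]


@dataclass(frozen=True)
class FRAPConfig:
    """Acquisition geometry and noise for one virtual FRAP experiment."""

    roi_diameter: float = 2.5    # µm
    n_prebleach: int = 5
    frame_interval: float = 1.5  # s
    n_postbleach: int = 100
    bleach_depth: float = 1.0    # fraction of ROI intensity removed
    noise_cv: float = 0.0        # relative (multiplicative) noise per frame

    def __post_init__(self) -> None:
        if self.roi_diameter <= 0:
            raise ConfigError("roi_diameter must be positive")
        if self.n_prebleach < 1:
            raise ConfigError("need at least one pre-bleach frame")
        if not (0.0 < self.bleach_depth <= 1.0):
            raise ConfigError("bleach_depth must lie in (0, 1]")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be positive")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be non-negative")


@dataclass
class FRAPCurve:
    """ROI-mean fluorescence over time; bleach at t = 0."""

    times: np.ndarray                  # s, strictly increasing
    intensity: np.ndarray              # raw ROI mean (a.u.)
    normalized: np.ndarray | None = None  # F_n(t); 0 at bleach, ~1 recovered
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FRAPFit:
    t_half: float           # s
    mobile_fraction: float  # %
    tau_model: float        # fitted recovery timescale (s)
    converged: bool
    model: str = "disk"


def soumpasis(t, tau_d: float):
    """Uniform-disk 2D-diffusion recovery f(t); f(0)=0, f(∞)=1.

    Evaluated with exponentially scaled Bessel functions for stability at
    small t (large argument).
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = 2.0 * tau_d / t[pos]
    out[pos] = ive(0, x) + ive(1, x)
    return out


@lru_cache(maxsize=None)
def _disk_half_x() -> float:
    """Argument x* where e^(−x)(I₀(x)+I₁(x)) = 1/2."""
    return brentq(lambda x: ive(0, x) + ive(1, x) - 0.5, 1e-6, 1e3)


def disk_half_time_factor() -> float:
    """t₁/₂ / τD for the uniform-disk recovery (= 2/x* ≈ 0.8946)."""
    return 2.0 / _disk_half_x()


def simulate_frap(d: float, mobile_fraction: float, config: FRAPConfig,
                  rng: np.random.Generator | None = None) -> FRAPCurve:
    """Generate one raw FRAP curve for diffusion coefficient ``d`` (µm²/s).

    Pre-bleach frames sit at 1; post-bleach frames follow
    (1 − depth) + depth·(M/100)·f(t) with f the disk recovery at
    τD = r²/(4·d).  Multiplicative Gaussian noise of CV ``noise_cv`` is
    applied to every frame.
    """
    if d <= 0:
        raise ConfigError("d must be positive")
    if not (0.0 <= mobile_fraction <= 100.0):
        raise ConfigError("mobile_fraction must lie in [0, 100]")
    r = config.roi_diameter / 2.0
    tau_d = r ** 2 / (4.0 * d)
    dtf = config.frame_interval
    t_pre = -dtf * np.arange(config.n_prebleach, 0, -1)
    t_post = dtf * np.arange(config.n_postbleach)
    f = soumpasis(t_post, tau_d)
    post = (1.0 - config.bleach_depth) + config.bleach_depth * (
        mobile_fraction / 100.0) * f
    intensity = np.concatenate([np.ones_like(t_pre), post])
    times = np.concatenate([t_pre, t_post])
    if config.noise_cv > 0:
        rng = np.random.default_rng() if rng is None else rng
        intensity = intensity * (1.0 + config.noise_cv *
                                 rng.standard_normal(intensity.size))
    return FRAPCurve(times=times, intensity=intensity,
                     meta={"tau_d_s": tau_d, "d_um2_s": d,
                           "mobile_fraction_pct": mobile_fraction,
                           "roi_diameter_um": config.roi_diameter})


def normalize_frap(raw: FRAPCurve) -> FRAPCurve:
    """Anchor the curve: mean pre-bleach → 1, first post-bleach frame → 0.

    F_n(t) = (F(t) − F₀)/(F_pre − F₀).  Pre-bleach frames are the ones at
    t < 0; their normalized mean is exactly 1 by construction.
    """
    pre = raw.times < 0
    post = ~pre
    if pre.sum() < 1 or post.sum() < 2:
        raise ConfigError("need >= 1 pre-bleach and >= 2 post-bleach frames")
    f_pre = float(raw.intensity[pre].mean())
    f0 = float(raw.intensity[post][0])
    denom = f_pre - f0
    if abs(denom) < 1e-12 * max(abs(f_pre), 1.0):
        raise DegenerateNormalizationError(
            "pre-bleach and first post-bleach levels coincide: no bleach")
    normalized = (raw.intensity - f0) / denom
    return FRAPCurve(times=raw.times.copy(), intensity=raw.intensity.copy(),
                     normalized=normalized, meta=dict(raw.meta))


def fit_frap(curve: FRAPCurve, model: str = "disk") -> FRAPFit:
    """Fit M·f(t) to the normalized post-bleach recovery.

    ``model`` selects the disk (Soumpasis) or "exp" single-exponential
    recovery shape.  Returns the mobile fraction in percent and the
    half-time of the fitted curve (time to M/2); a flat curve (M → 0) has
    no defined half-time and reports t_half = nan.
    """
    if model not in ("disk", "exp"):
        raise ConfigError("model must be 'disk' or 'exp'")
    if curve.normalized is None:
        curve = normalize_frap(curve)
    post = curve.times >= 0
    t = curve.times[post]
    y = curve.normalized[post]
    if t.size < 10:
        raise UnderdeterminedFitError("need >= 10 post-bleach frames")

    plateau0 = float(np.clip(np.mean(y[-max(3, t.size // 10):]), 1e-3, 1.0))
    half = plateau0 / 2.0
    above = np.nonzero(y >= half)[0]
    t_half0 = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(
        t[t.size // 4])
    params = lmfit.Parameters()
    params.add("mobile", value=plateau0, min=0.0, max=1.0)
    if model == "disk":
        params.add("tau", value=max(t_half0 / disk_half_time_factor(), 1e-6),
                   min=1e-9)

        def shape(tau):
            return soumpasis(t, tau)
    else:
        params.add("tau", value=max(t_half0 / np.log(2.0), 1e-6), min=1e-9)

        def shape(tau):
            return 1.0 - np.exp(-t / tau)

    def residual(p):
        return p["mobile"] * shape(p["tau"].value) - y

    try:
        result = lmfit.minimize(residual, params, method="leastsq")
        ok = bool(result.success)
    except Exception:
        return FRAPFit(t_half=np.nan, mobile_fraction=np.nan,
                       tau_model=np.nan, converged=False, model=model)
    mobile = float(result.params["mobile"].value)
    tau = float(result.params["tau"].value)
    if mobile < 1e-6:
        t_half = np.nan
    elif model == "disk":
        t_half = disk_half_time_factor() * tau
    else:
        t_half = tau * np.log(2.0)
    return FRAPFit(t_half=t_half, mobile_fraction=100.0 * mobile,
                   tau_model=tau, converged=ok, model=model)
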