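"""Fitting the 2D lateral diffusion model to autocorrelation curves.

The model is the single-component free-diffusion ACF for a Gaussian spot in
a planar membrane,

    G(τ) = baseline + amplitude · (1 + τ/τd)⁻¹ ,

with τd the mean dwell (diffusion) time in the spot and amplitude ≈ 1/N the
inverse mean spot occupancy.  No triplet term and no anomalous exponent are
included.  Spot waists are calibrated from the fitted diffusion time of a
reference dye of known diffusion coefficient via ω = √(4·D_ref·τd_ref).
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

from .errors import ConfigError, UnderdeterminedFitError
from .fcs import ACFCurve

__all__ = [
    "ACFModelFit", "WaistCalibration",
    "model_g", "fit_acf", "calibrate_waist", "RHODAMINE6G_D",
]

#: literature lateral diffusion coefficient of Rhodamine 6G in water at
#: 25 °C (µm²/s); the default reference for waist calibration
RHODAMINE6G_D = 414.0


@dataclass(frozen=True)
class ACFModelFit:
    """Result of a 2D-diffusion model fit to one ACF curve."""

    tau_d: float          # s
    amplitude: float      # G(0) excess above baseline (~1/N)
    baseline: float       # G at infinite lag
    tau_d_err: float      # s, standard error from the fit covariance
    chi2_reduced: float
    converged: bool


@dataclass(frozen=True)
class WaistCalibration:
    waist: float      # µm
    d_ref: float      # µm²/s
    tau_d_ref: float  # s


def model_g(lag, amplitude: float, tau_d: float, baseline: float):
    """2D lateral diffusion ACF, G(τ) = baseline + amplitude/(1 + τ/τd)."""
    if tau_d <= 0:
        raise ConfigError("tau_d must be positive")
    return baseline + amplitude / (1.0 + np.asarray(lag) / tau_d)


def _initial_guess(lags: np.ndarray, g: np.ndarray) -> tuple[float, float, float]:
    """Derivative-free seeds: baseline from the last lag decade, amplitude
    from the early plateau, τd from the half-amplitude crossing."""
    tail = g[lags >= lags[-1] / 10.0]
    baseline0 = float(np.median(tail)) if tail.size else float(g[-1])
    amp0 = float(np.max(g) - baseline0)
    if amp0 <= 0:
        amp0 = max(float(np.max(g) - np.min(g)), 1e-6)
    half = baseline0 + 0.5 * amp0
    below = np.nonzero(g <= half)[0]
    tau0 = float(lags[below[0]]) if below.size else float(np.median(lags))
    tau0 = max(tau0, float(lags[0]))
    return amp0, tau0, baseline0


def fit_acf(curve: ACFCurve, init: dict | None = None,
            min_lag: float = 0.0, max_lag: float = np.inf) -> ACFModelFit:
    """Weighted least-squares fit of the 2D diffusion model to ``curve``.

    Weights are 1/g_err² when every selected lag carries a positive error
    estimate, else the fit is unweighted.  Lags outside [min_lag, max_lag]
    are excluded (the caller typically drops lags below ~3 sampling bins,
    where shot-noise artifacts live).  A stalled optimizer is reported via
    ``converged=False``, never an exception.
    """
    sel = (curve.lags >= min_lag) & (curve.lags <= max_lag) & (curve.lags > 0)
    lags = np.asarray(curve.lags[sel], dtype=float)
    g = np.asarray(curve.g[sel], dtype=float)
    if lags.size < 3:
        raise UnderdeterminedFitError(
            f"{lags.size} lags cannot constrain a 3-parameter model")
    amp0, tau0, base0 = _initial_guess(lags, g)
    if init:
        amp0 = init.get("amplitude", amp0)
        tau0 = init.get("tau_d", tau0)
        base0 = init.get("baseline", base0)
    params = lmfit.Parameters()
    params.add("amplitude", value=amp0, min=0.0)
    params.add("tau_d", value=tau0, min=lags[0] * 1e-4)
    params.add("baseline", value=base0)

    weights = None
    if curve.g_err is not None:
        err = np.asarray(curve.g_err[sel], dtype=float)
        if np.all(err > 0):
            weights = 1.0 / err

    def residual(p):
        r = p["baseline"] + p["amplitude"] / (1.0 + lags / p["tau_d"]) - g
        return r * weights if weights is not None else r

    try:
        result = lmfit.minimize(residual, params, method="leastsq")
        ok = bool(result.success)
    except Exception:
        result = None
        ok = False
    if result is None:
        return ACFModelFit(tau_d=np.nan, amplitude=np.nan, baseline=np.nan,
                           tau_d_err=np.nan, chi2_reduced=np.nan,
                           converged=False)
    p = result.params
    tau_err = p["tau_d"].stderr
    return ACFModelFit(
        tau_d=float(p["tau_d"].value),
        amplitude=float(p["amplitude"].value),
        baseline=float(p["baseline"].value),
        tau_d_err=float(tau_err) if tau_err is not None else np.nan,
        chi2_reduced=float(result.redchi),
        converged=ok and p["tau_d"].value > 0,
    )


def calibrate_waist(tau_d_ref: float, d_ref: float = RHODAMINE6G_D,
                    ) -> WaistCalibration:
    """Spot waist from the fitted diffusion time of a reference dye.

    Inverts the free-diffusion law τd = ω²/(4D): ω = √(4·D_ref·τd_ref).
    """
    if tau_d_ref <= 0 or d_ref <= 0:
        raise ConfigError("tau_d_ref and d_ref must be positive")
    return WaistCalibration(waist=float(np.sqrt(4.0 * d_ref * tau_d_ref)),
                            d_ref=d_ref, tau_d_ref=tau_d_ref)
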