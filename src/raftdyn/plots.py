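"""Matplotlib figures: diffusion laws and FRAP recovery curves."""

from __future__ import annotations

import numpy as np

from .diffusion_law import DiffusionLaw
from .frap import FRAPCurve, FRAPFit, disk_half_time_factor, soumpasis


def plot_diffusion_law(law: DiffusionLaw, ax=None, label: str | None = None,
                       color=None):
    """τd vs ω² with the fitted line extrapolated to the t₀ intercept."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.array([p.waist_sq for p in law.points])
    y = np.array([p.tau_d_mean for p in law.points])
    yerr = np.array([p.tau_d_sem for p in law.points])
    line = ax.errorbar(x, y, yerr=yerr, fmt="o", capsize=3, color=color,
                       label=label)
    color = line.lines[0].get_color()
    xx = np.linspace(0, x.max() * 1.05, 50)
    slope = 1000.0 / (4.0 * law.d_eff)
    ax.plot(xx, law.t0 + slope * xx, "-", color=color, alpha=0.7)
    ax.axhline(0, color="0.6", lw=0.8)
    ax.set_xlabel(r"$\omega^2$ [$\mu$m$^2$]")
    ax.set_ylabel(r"$\tau_d$ [ms]")
    ax.annotate(f"$t_0$ = {law.t0:.2f} ± {law.t0_sem:.2f} ms ({law.regime})",
                xy=(0.03, 0.92), xycoords="axes fraction", fontsize=8)
    return ax


def plot_frap(curve: FRAPCurve, fit: FRAPFit | None = None, ax=None):
    """Normalized recovery vs time, optionally with the fitted model."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    y = curve.normalized if curve.normalized is not None else curve.intensity
    ax.plot(curve.times, y, ".", ms=3, label="data")
    if fit is not None and np.isfinite(fit.tau_model):
        t = np.linspace(0, curve.times.max(), 200)
        if fit.model == "disk":
            model = fit.mobile_fraction / 100.0 * soumpasis(t, fit.tau_model)
        else:
            model = fit.mobile_fraction / 100.0 * (1 - np.exp(-t / fit.tau_model))
        ax.plot(t, model, "-", label=(
            f"fit: $t_{{1/2}}$ = {fit.t_half:.2f} s, "
            f"M = {fit.mobile_fraction:.1f} %"))
        ax.legend(fontsize=8)
    ax.set_xlabel("time [s]")
    ax.set_ylabel("normalized fluorescence")
    return ax
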