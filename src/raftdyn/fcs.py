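"""Virtual confocal detection and autocorrelation estimation.

A Gaussian observation spot of 1/e² radius ω (the waist) converts particle
trajectories into a binned fluorescence intensity trace; the normalized
fluctuation autocorrelation G(τ) = ⟨δF(t)δF(t+τ)⟩/⟨F⟩² is then estimated
either with a hardware-correlator-style multi-tau scheme (quasi-logarithmic
lag grid, m linear channels per stage, bin width doubled each stage) or with
the brute-force O(N·max_lag) estimator used as its oracle.  Both use the
symmetric normalization ⟨F₁F₂⟩/(⟨F₁⟩⟨F₂⟩) − 1, where the two means run over
the left- and right-shifted halves of the overlap, which keeps slow drifts
from inflating the plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import _spot_signal
from .errors import ConfigError, DegenerateTraceError
from .sim import TrajectoryEnsemble

__all__ = [
    "DetectionProfile", "IntensityTrace", "ACFCurve",
    "intensity_trace", "multitau_acf", "direct_acf", "average_runs",
]


@dataclass(frozen=True)
class DetectionProfile:
    """Gaussian confocal spot: detected signal ∝ exp(−2·|r−center|²/ω²)."""

    waist: float                 # ω, 1/e² radius (µm)
    center: tuple[float, float]  # spot center (µm)
    brightness: float            # expected counts / particle at center / bin
    background: float = 0.0      # expected counts / bin

    def __post_init__(self) -> None:
        if self.waist <= 0:
            raise ConfigError("waist must be positive")
        if self.brightness <= 0:
            raise ConfigError("brightness must be positive")
        if self.background < 0:
            raise ConfigError("background must be non-negative")


@dataclass
class IntensityTrace:
    counts: np.ndarray   # per-bin detected counts (or expected signal)
    bin_time: float      # s
    duration: float      # s
    run_id: int = 0
    cell_id: int = 0


@dataclass
class ACFCurve:
    lags: np.ndarray               # s, strictly increasing, lag > 0
    g: np.ndarray                  # G(τ)
    g_err: np.ndarray | None = None  # per-lag standard error across runs
    n_runs: int = 1
    meta: dict = field(default_factory=dict)


def intensity_trace(ensemble: TrajectoryEnsemble, profile: DetectionProfile,
                    bin_time: float, rng: np.random.Generator | None = None,
                    poisson: bool = True, run_id: int = 0, cell_id: int = 0,
                    ) -> IntensityTrace:
    """Detect an ensemble through a Gaussian spot and bin into counts.

    The expected signal per bin is background + brightness·Σ_i w_i averaged
    over the frames inside the bin, with w_i the Gaussian detection weight
    at the minimum-image distance of particle i from the spot center.
    Counts are Poisson-distributed around that expectation; with
    ``poisson=False`` the expectation itself is returned (noise-free mode).
    """
    ratio = bin_time / ensemble.dt
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-9:
        raise ConfigError("bin_time must be a positive integer multiple of dt")
    pos = np.ascontiguousarray(np.swapaxes(ensemble.positions, 0, 1))  # (F,P,2)
    n_frames = pos.shape[0]
    signal = np.empty(n_frames)
    _spot_signal(pos, profile.center[0], profile.center[1],
                 2.0 / profile.waist ** 2, ensemble.box_size, signal)
    n_bins = n_frames // k
    lam = profile.background + profile.brightness * (
        signal[: n_bins * k].reshape(n_bins, k).mean(axis=1))
    if poisson:
        rng = np.random.default_rng() if rng is None else rng
        counts = rng.poisson(lam).astype(float)
    else:
        counts = lam
    return IntensityTrace(counts=counts, bin_time=bin_time,
                          duration=n_bins * bin_time,
                          run_id=run_id, cell_id=cell_id)


def _sym_corr(x: np.ndarray, k: int) -> float:
    """Symmetrically normalized correlation of x at integer lag k >= 0."""
    if k == 0:
        m = x.mean()
        return float(np.mean(x * x) / (m * m) - 1.0)
    left = x[:-k]
    right = x[k:]
    return float(np.mean(left * right) / (left.mean() * right.mean()) - 1.0)


def _check_not_constant(counts: np.ndarray) -> None:
    if counts.size == 0 or np.all(counts == counts[0]):
        raise DegenerateTraceError(
            "constant trace has zero variance; correlation undefined")


def multitau_acf(trace: IntensityTrace, m: int = 16) -> ACFCurve:
    """Multi-tau autocorrelation on a quasi-logarithmic lag grid.

    Stage 0 evaluates lags 1..m at the native bin width; every further
    stage halves the time resolution (adjacent-bin averaging) and evaluates
    lags m/2+1..m in units of the doubled width, i.e. the classic
    hardware-correlator layout with m channels per stage.
    """
    if m < 2 or m % 2:
        raise ConfigError("m must be an even integer >= 2")
    counts = np.asarray(trace.counts, dtype=float)
    if counts.size < 2 * m:
        raise ConfigError("trace too short for the requested channel count")
    _check_not_constant(counts)
    lags: list[float] = []
    g: list[float] = []
    x = counts
    width = 1
    stage = 0
    while x.size >= 2 * m:
        ks = range(1, m + 1) if stage == 0 else range(m // 2 + 1, m + 1)
        for k in ks:
            if k >= x.size:
                break
            lags.append(k * width * trace.bin_time)
            g.append(_sym_corr(x, k))
        n2 = x.size // 2
        x = 0.5 * (x[: 2 * n2 : 2] + x[1 : 2 * n2 : 2])
        width *= 2
        stage += 1
    return ACFCurve(lags=np.asarray(lags), g=np.asarray(g),
                    meta={"estimator": "multitau", "m": m,
                          "bin_time_s": trace.bin_time})


def direct_acf(trace: IntensityTrace, max_lag: int) -> ACFCurve:
    """Brute-force lag-by-lag estimator of the same normalized ACF.

    Includes lag 0, where G(0) = Var(F)/⟨F⟩² (population variance).  Used
    as the independent oracle for :func:`multitau_acf`.
    """
    counts = np.asarray(trace.counts, dtype=float)
    if max_lag >= counts.size:
        raise ConfigError("max_lag must be smaller than the trace length")
    _check_not_constant(counts)
    ks = np.arange(0, max_lag + 1)
    g = np.array([_sym_corr(counts, int(k)) for k in ks])
    return ACFCurve(lags=ks * trace.bin_time, g=g,
                    meta={"estimator": "direct",
                          "bin_time_s": trace.bin_time})


def average_runs(curves: list[ACFCurve]) -> ACFCurve:
    """Per-lag mean and standard error over repeated acquisition runs."""
    if not curves:
        raise ConfigError("need at least one curve")
    lags = curves[0].lags
    for c in curves[1:]:
        if c.lags.shape != lags.shape or not np.allclose(c.lags, lags):
            raise ConfigError("curves must share an identical lag grid")
    stack = np.vstack([c.g for c in curves])
    n = len(curves)
    mean = stack.mean(axis=0)
    err = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    meta = dict(curves[0].meta)
    return ACFCurve(lags=lags.copy(), g=mean, g_err=err, n_runs=n, meta=meta)
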