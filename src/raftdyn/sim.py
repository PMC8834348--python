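"""Monte Carlo simulation of probe diffusion in a nanodomain-containing membrane.

The membrane is a periodic 2D square box containing non-overlapping circular
trapping domains (radius well below 100 nm, emulating raft nanodomains).
Outside the domains a probe performs free Brownian motion with coefficient
``d_out``; inside, with the reduced coefficient ``d_in``.  A step that would
carry the probe across a domain boundary is accepted with probability
``p_enter`` (entering) or ``p_escape`` (leaving) and otherwise reflected off
the boundary, which produces transient trapping: probes partition into
domains for stochastic residence periods, the microscopic mechanism behind a
positive intercept of the spot-variation FCS diffusion law.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import _advance, _locate
from .errors import ConfigError, MemoryGuardError, PackingError

__all__ = [
    "SimulationConfig",
    "DomainMap",
    "TrajectoryEnsemble",
    "SimState",
    "init_domains",
    "step_ensemble",
    "simulate",
    "msd",
    "mean_residence_time",
    "domain_occupancy",
]

#: cap on positions array size (floats) admitted by :func:`simulate`
MAX_ENSEMBLE_FLOATS = 300_000_000


@dataclass(frozen=True)
class SimulationConfig:
    """Physical and numerical parameters of one membrane simulation.

    Lengths are in µm, times in s, diffusion coefficients in µm²/s.
    ``p_enter``/``p_escape`` are per-attempt crossing probabilities for a
    step that would traverse a domain boundary.
    """

    box_size: float
    n_particles: int
    dt: float
    duration: float
    d_out: float
    d_in: float
    p_enter: float
    p_escape: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box_size <= 0:
            raise ConfigError("box_size must be positive")
        if self.dt <= 0 or self.duration <= 0:
            raise ConfigError("dt and duration must be positive")
        if self.n_particles < 1:
            raise ConfigError("need at least one particle")
        if not (0 < self.d_in <= self.d_out):
            raise ConfigError("require 0 < d_in <= d_out")
        for name in ("p_enter", "p_escape"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if np.sqrt(2.0 * self.d_out * self.dt) > self.box_size / 10.0:
            raise ConfigError(
                "dt too coarse: rms step exceeds box_size/10; reduce dt")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def step_sigma_out(self) -> float:
        """Per-axis step standard deviation outside domains, √(2·d_out·dt)."""
        return float(np.sqrt(2.0 * self.d_out * self.dt))


@dataclass(frozen=True)
class DomainMap:
    """Geometry of the trapping nanodomains: disk centers and common radius."""

    centers: np.ndarray  # (n_domains, 2), µm
    radius: float        # µm
    box_size: float      # µm

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "centers", c)
        if c.size and (c.min() < 0 or c.max() >= self.box_size):
            raise ConfigError("domain centers must lie inside the box")
        if self.n_domains and self.radius <= 0:
            raise ConfigError("domain radius must be positive")

    @property
    def n_domains(self) -> int:
        return int(self.centers.shape[0])

    @property
    def area_fraction(self) -> float:
        return self.n_domains * np.pi * self.radius ** 2 / self.box_size ** 2

    @classmethod
    def empty(cls, box_size: float) -> "DomainMap":
        return cls(centers=np.empty((0, 2)), radius=0.0, box_size=box_size)

    def _grid(self) -> tuple[int, float, np.ndarray, np.ndarray]:
        """Spatial hash (cell size >= radius) for O(1) membership queries."""
        if self.n_domains == 0:
            return 1, self.box_size, np.zeros(2, dtype=np.int64), np.empty(0, dtype=np.int64)
        ncell = max(1, min(128, int(self.box_size / max(self.radius, 1e-9))))
        cell_size = self.box_size / ncell
        ix = np.minimum((self.centers[:, 0] / cell_size).astype(np.int64), ncell - 1)
        iy = np.minimum((self.centers[:, 1] / cell_size).astype(np.int64), ncell - 1)
        flat = ix * ncell + iy
        order = np.argsort(flat, kind="stable")
        counts = np.bincount(flat, minlength=ncell * ncell)
        start = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        return ncell, cell_size, start, order.astype(np.int64)

    def locate(self, xy: np.ndarray) -> np.ndarray:
        """Domain index (or -1) for each position in ``xy`` of shape (n, 2)."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        ncell, cell_size, start, items = self._grid()
        out = np.empty(len(xy), dtype=np.int64)
        r2 = self.radius ** 2
        for k, (x, y) in enumerate(xy):
            out[k] = _locate(x, y, self.centers, r2, self.box_size,
                             ncell, cell_size, start, items)
        return out


@dataclass
class SimState:
    """Mutable particle state carried between simulation segments."""

    positions: np.ndarray  # (P, 2)
    dom: np.ndarray        # (P,) int64, -1 = outside


@dataclass
class TrajectoryEnsemble:
    """Positions of all particles over time, with domain membership flags."""

    positions: np.ndarray   # (particle, frame, 2), µm, wrapped into [0, box)
    in_domain: np.ndarray   # (particle, frame) bool
    dt: float               # s
    box_size: float         # µm
    final_state: SimState | None = field(default=None, repr=False)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]


def init_domains(config: SimulationConfig, target_area_fraction: float,
                 radius: float, rng: np.random.Generator | None = None,
                 max_rejects: int = 100_000) -> DomainMap:
    """Place non-overlapping trapping disks by rejection sampling.

    The number of disks is round(f·L²/(πr²)), which keeps the achieved
    area fraction within 1 % of the target.  Raises :class:`PackingError`
    when the requested density cannot be packed within ``max_rejects``
    rejected placements.
    """
    if not (0.0 <= target_area_fraction < 0.5):
        raise ConfigError("target_area_fraction must lie in [0, 0.5)")
    if target_area_fraction > 0 and not (0 < radius < config.box_size / 4):
        raise ConfigError("radius must lie in (0, box_size/4)")
    if target_area_fraction == 0.0:
        return DomainMap.empty(config.box_size)
    rng = np.random.default_rng(config.seed) if rng is None else rng
    box = config.box_size
    n = int(round(target_area_fraction * box ** 2 / (np.pi * radius ** 2)))
    centers: list[np.ndarray] = []
    placed = np.empty((0, 2))
    rejects = 0
    min_d2 = (2.0 * radius) ** 2
    while len(centers) < n:
        cand = rng.uniform(0.0, box, size=2)
        if len(centers):
            d = placed - cand
            d -= box * np.round(d / box)  # periodic minimum image
            if np.min(np.einsum("ij,ij->i", d, d)) < min_d2:
                rejects += 1
                if rejects >= max_rejects:
                    raise PackingError(
                        f"could not place {n} disks of radius {radius} at "
                        f"area fraction {target_area_fraction}")
                continue
        centers.append(cand)
        placed = np.asarray(centers)
    dom = DomainMap(centers=placed, radius=radius, box_size=box)
    achieved = dom.area_fraction
    if abs(achieved - target_area_fraction) > 0.01 * max(target_area_fraction, 1e-12):
        raise PackingError(
            f"achieved area fraction {achieved:.4f} deviates more than 1 % "
            f"from target {target_area_fraction:.4f}")
    return dom


def _prepare_state(config: SimulationConfig, domains: DomainMap,
                   rng: np.random.Generator) -> SimState:
    pos = rng.uniform(0.0, config.box_size, size=(config.n_particles, 2))
    dom = domains.locate(pos)
    return SimState(positions=pos, dom=dom)


def step_ensemble(state: SimState, config: SimulationConfig, domains: DomainMap,
                  rng: np.random.Generator, n_steps: int = 1,
                  ) -> TrajectoryEnsemble:
    """Advance ``state`` by ``n_steps`` Brownian steps (state is mutated).

    Returns the recorded frames as a :class:`TrajectoryEnsemble`; the frame
    at index f is the configuration after step f+1.
    """
    n_part = state.positions.shape[0]
    # float32 variates: halves RNG cost and memory; step precision ~1e-7
    # relative, far below any observable statistic here
    normals = rng.standard_normal((n_steps, n_part, 2), dtype=np.float32)
    if domains.n_domains:
        unifs = rng.random((n_steps, n_part), dtype=np.float32)
    else:  # no boundaries to cross; acceptance draws are never consumed
        unifs = np.empty((0, n_part), dtype=np.float32)
    out_pos = np.empty((n_steps, n_part, 2))
    out_in = np.empty((n_steps, n_part), dtype=np.bool_)
    ncell, cell_size, start, items = domains._grid()
    _advance(state.positions, state.dom, normals, unifs,
             np.sqrt(2.0 * config.d_out * config.dt),
             np.sqrt(2.0 * config.d_in * config.dt),
             config.p_enter, config.p_escape,
             config.box_size, domains.centers, domains.radius,
             ncell, cell_size, start, items, out_pos, out_in)
    return TrajectoryEnsemble(
        positions=np.swapaxes(out_pos, 0, 1),
        in_domain=np.swapaxes(out_in, 0, 1),
        dt=config.dt, box_size=config.box_size,
        final_state=state)


def simulate(config: SimulationConfig, domains: DomainMap | None = None,
             rng: np.random.Generator | None = None,
             initial_state: SimState | None = None,
             burn_in: float = 0.0) -> TrajectoryEnsemble:
    """Run the full simulation defined by ``config``.

    Reproducible: a fixed ``config.seed`` (and no external rng) yields
    bit-identical ensembles.  ``burn_in`` seconds are simulated and
    discarded before recording starts, which lets the domain occupancy
    relax to its stationary value when trapping is present.
    ``initial_state`` (e.g. the ``final_state`` of a previous segment)
    allows consecutive acquisitions on the same virtual cell.
    """
    domains = DomainMap.empty(config.box_size) if domains is None else domains
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_frames = config.n_frames
    if 2 * n_frames * config.n_particles > MAX_ENSEMBLE_FLOATS:
        raise MemoryGuardError(
            f"{n_frames} frames x {config.n_particles} particles exceeds the "
            "in-memory cap; simulate in shorter segments")
    state = initial_state if initial_state is not None else _prepare_state(
        config, domains, rng)
    if burn_in > 0:
        step_ensemble(state, config, domains, rng,
                      n_steps=int(round(burn_in / config.dt)))
    return step_ensemble(state, config, domains, rng, n_steps=n_frames)


def msd(ensemble: TrajectoryEnsemble, max_lag: int = 100,
        origin_stride: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Time-and-ensemble averaged mean squared displacement.

    Wrapped positions are unwrapped with the minimum-image convention
    (valid because single steps are far smaller than the box).  Returns
    (lag times in s, MSD in µm²) for lags 1..max_lag frames.
    """
    pos = ensemble.positions
    box = ensemble.box_size
    d = np.diff(pos, axis=1)
    d -= box * np.round(d / box)
    unwrapped = np.concatenate([pos[:, :1], pos[:, :1] + np.cumsum(d, axis=1)],
                               axis=1)
    n_frames = unwrapped.shape[1]
    lags = np.arange(1, max_lag + 1)
    out = np.empty(max_lag)
    for k, lag in enumerate(lags):
        origins = np.arange(0, n_frames - lag, origin_stride)
        disp = unwrapped[:, origins + lag] - unwrapped[:, origins]
        out[k] = np.mean(np.sum(disp ** 2, axis=-1))
    return lags * ensemble.dt, out


def mean_residence_time(ensemble: TrajectoryEnsemble) -> float:
    """Mean duration (s) of uninterrupted in-domain episodes.

    Episodes touching the start or end of the record are included, so the
    value is slightly biased downward for residence times comparable to the
    record length; adequate for comparisons at fixed duration.
    """
    flags = ensemble.in_domain
    total = 0.0
    count = 0
    for row in flags:
        padded = np.concatenate([[False], row, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[::2], edges[1::2]
        total += float(np.sum(ends - starts))
        count += len(starts)
    if count == 0:
        return 0.0
    return total * ensemble.dt / count


def domain_occupancy(ensemble: TrajectoryEnsemble) -> float:
    """Time-averaged fraction of particles inside any domain."""
    return float(np.mean(ensemble.in_domain))
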