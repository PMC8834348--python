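"""Condition presets for the virtual experiments.

Each preset names one experimental group (probe x perturbation) and carries
up to three parameter sets, loaded from the versioned ``data/presets.yaml``:

* ``law``  — ground-truth diffusion-law line (t0 in ms, D_eff in µm²/s),
* ``frap`` — ground-truth recovery (t_1/2 in s, mobile fraction in %),
* ``sim``  — microscopic Monte Carlo parameters producing the corresponding
  confinement behavior (tuned once; documented in docs/methods.md).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache

import yaml

from .errors import UnknownConditionError
from .sim import SimulationConfig

__all__ = [
    "CONDITIONS", "DomainSpec", "LawParams", "FrapParams",
    "load_presets", "preset", "law_params", "frap_params",
]

CONDITIONS = (
    "SM_control", "SM_KnD", "SM_ZA_Myr", "SM_rescue",
    "PC_control", "PC_KnD",
    "Thy1_control", "Thy1_KnD",
    "Flot2_control", "Flot2_KnD", "Flot2_MbCD",
)


@dataclass(frozen=True)
class DomainSpec:
    """Domain-placement parameters accompanying a SimulationConfig."""

    radius: float          # µm
    area_fraction: float
    burn_in: float         # s of equilibration before recording


@dataclass(frozen=True)
class LawParams:
    t0_ms: float
    t0_sem_ms: float
    d_eff: float
    d_eff_sem: float


@dataclass(frozen=True)
class FrapParams:
    t_half_s: float
    t_half_sd_s: float
    mobile_fraction_pct: float
    mobile_fraction_sd: float


@lru_cache(maxsize=1)
def load_presets() -> dict:
    """Parsed contents of the packaged presets.yaml."""
    ref = importlib.resources.files("raftdyn.data") / "presets.yaml"
    return yaml.safe_load(ref.read_text())


def _entry(condition: str) -> dict:
    data = load_presets()
    try:
        return data["conditions"][condition]
    except KeyError:
        raise UnknownConditionError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}")


def law_params(condition: str) -> LawParams:
    """Ground-truth diffusion-law parameters for a svFCS condition."""
    entry = _entry(condition)
    if "law" not in entry:
        raise UnknownConditionError(
            f"condition {condition!r} has no diffusion-law ground truth")
    return LawParams(**entry["law"])


def frap_params(condition: str) -> FrapParams:
    """Ground-truth FRAP parameters for a photobleaching condition."""
    entry = _entry(condition)
    if "frap" not in entry:
        raise UnknownConditionError(
            f"condition {condition!r} has no FRAP ground truth")
    return FrapParams(**entry["frap"])


def preset(condition: str, n_particles: int | None = None,
           duration: float = 5.0, seed: int = 0,
           ) -> tuple[SimulationConfig, DomainSpec]:
    """Microscopic simulation parameters for ``condition``.

    Returns the simulation configuration together with the domain-placement
    spec (radius, target area fraction, equilibration time).
    """
    data = load_presets()
    entry = _entry(condition)
    sim = entry["sim"]
    defaults = data["defaults"]
    config = SimulationConfig(
        box_size=float(sim.get("box_um", defaults["box_um"])),
        n_particles=int(n_particles if n_particles is not None
                        else sim.get("n_particles", defaults["n_particles"])),
        dt=float(sim["dt_s"]),
        duration=float(duration),
        d_out=float(sim["d_out"]),
        d_in=float(sim["d_in"]),
        p_enter=float(sim["p_enter"]),
        p_escape=float(sim["p_escape"]),
        seed=int(seed),
    )
    spec = DomainSpec(
        radius=float(sim.get("radius_um", defaults["radius_um"])),
        area_fraction=float(sim["area_fraction"]),
        burn_in=float(sim.get("burn_in_s", defaults["burn_in_s"])),
    )
    return config, spec
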