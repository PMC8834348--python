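import numpy as np
import pytest

from raftdyn.sim import SimulationConfig, TrajectoryEnsemble


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def free_config():
    """Domain-free Brownian motion at D = 1 µm²/s in a 3 µm box."""
    return SimulationConfig(box_size=3.0, n_particles=200, dt=1e-4,
                            duration=0.5, d_out=1.0, d_in=1.0,
                            p_enter=1.0, p_escape=1.0, seed=7)


def make_static_ensemble(positions, n_frames=50, dt=1e-4, box=3.0):
    """Ensemble of immobile particles at fixed positions (for detector tests)."""
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    stack = np.repeat(pos[:, None, :], n_frames, axis=1)
    return TrajectoryEnsemble(
        positions=stack,
        in_domain=np.zeros((pos.shape[0], n_frames), dtype=bool),
        dt=dt, box_size=box)


@pytest.fixture
def static_ensemble_factory():
    return make_static_ensemble
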