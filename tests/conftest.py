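import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pgcsim import ModelParameters, Trajectory

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def free_particle_params(**overrides) -> ModelParameters:
    """One non-interacting particle in a very wide channel: no neighbours,
    no wall contact — the configuration where speed is exactly v0."""
    defaults = dict(
        n_particles=1,
        adhesion_epsilon=0.0,
        boundary_mode="non_reflective",
        channel_width=1000.0,
        channel_length=1000.0,
        t_total=200.0,
        t_steady_start=0.0,
        t_steady_end=200.0,
        save_interval=1.0,
        seed=0,
    )
    defaults.update(overrides)
    return ModelParameters(**defaults)


def make_trajectory(positions, times=None, params=None, angles=None) -> Trajectory:
    """Assemble a Trajectory from raw arrays (for analysis-only tests)."""
    positions = np.asarray(positions, dtype=float)
    n_frames, n, _ = positions.shape
    if times is None:
        times = np.arange(n_frames) * 5.0
    if params is None:
        params = ModelParameters(n_particles=n)
    if angles is None:
        angles = np.zeros((n_frames, n))
    save = float(times[1] - times[0]) if n_frames > 1 else params.save_interval
    return Trajectory(params, np.asarray(times, float), positions, np.asarray(angles, float), save)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
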