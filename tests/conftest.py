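import numpy as np
import pytest

from gaitpipe.kinematics import compute_angles
from gaitpipe.synthetic import SimulationConfig, simulate_subject


@pytest.fixture(scope="session")
def zero_noise_config() -> SimulationConfig:
    """Deterministic gait: no pixel noise, no drops, fixed cycle time."""
    return SimulationConfig(
        pixel_noise_sd=0.0,
        missing_frame_rate=0.0,
        cycle_time_cv=0.0,
        amplitude_jitter_sd=0.0,
    )


@pytest.fixture(scope="session")
def clean_subject(zero_noise_config):
    """One noiseless simulated subject (trajectory, ground truth)."""
    return simulate_subject(zero_noise_config, subject_id="clean", seed=11)


@pytest.fixture(scope="session")
def clean_series(clean_subject):
    trajectory, _ = clean_subject
    return compute_angles(trajectory)


@pytest.fixture(scope="session")
def noisy_subject():
    """One subject under the default (moderate) noise model."""
    return simulate_subject(SimulationConfig(), subject_id="noisy", seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
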