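import numpy as np
import pytest

from neargaze.pupil import PupilDetector
from neargaze.synthetic import SceneConfig, simulate_calibration_session


@pytest.fixture(scope="session")
def detector():
    return PupilDetector()


@pytest.fixture(scope="session")
def default_config():
    """Nominal recording conditions: 1 px jitter, 5% blinks, sigma-6 noise."""
    return SceneConfig(seed=7)


@pytest.fixture(scope="session")
def noiseless_config():
    return SceneConfig(jitter_sigma_px=0.0, blink_prob=0.0, noise_sigma=0.0,
                       seed=7)


@pytest.fixture(scope="session")
def calibration_session(default_config):
    """One full 9-mark x 60-frame calibration recording (rendered once)."""
    return simulate_calibration_session(default_config)


@pytest.fixture(scope="session")
def small_noiseless_session(noiseless_config):
    """A quick 9-mark x 5-frame noiseless recording for exact-path tests."""
    return simulate_calibration_session(noiseless_config, frames_per_mark=5)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
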