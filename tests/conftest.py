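import numpy as np
import pytest

from gaitval.config import SyntheticConfig
from gaitval.synthetic import generate_scenario


@pytest.fixture(scope="session")
def clean_config() -> SyntheticConfig:
    """Noiseless, jitter-free walking bout: the exact round-trip reference."""
    return SyntheticConfig(
        seed=11,
        stride_cv=0.0,
        gyro_noise_sd_dps=0.0,
        glitch_probability=0.0,
        clock_offset_s=0.17,
    )


@pytest.fixture(scope="session")
def clean_scenario(clean_config):
    """(truth, gyro, series, keypoints, segment) for the clean bout."""
    return generate_scenario(clean_config)


@pytest.fixture(scope="session")
def noisy_config() -> SyntheticConfig:
    """Moderate-noise study conditions: 5% stride CV, 10 deg/s gyro noise."""
    return SyntheticConfig(seed=12, stride_cv=0.05, gyro_noise_sd_dps=10.0)


@pytest.fixture(scope="session")
def noisy_scenario(noisy_config):
    return generate_scenario(noisy_config)


def nearest_errors(estimates: np.ndarray, truths: np.ndarray) -> np.ndarray:
    """|nearest estimate − truth| for each truth event."""
    estimates = np.asarray(estimates, float)
    return np.array([np.min(np.abs(estimates - t)) for t in np.asarray(truths, float)])
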