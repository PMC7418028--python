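import pytest

from dualclumped import default_calibration
from dualclumped.synthetic import SimulationConfig


@pytest.fixture(scope="session")
def cal():
    return default_calibration()


@pytest.fixture
def quiet_config():
    """Session config with every distortion and noise source switched off."""
    return SimulationConfig(
        scaling_factors=(0.0, 0.0, 0.0),
        i47_5_mv=0.0,
        transfer_slope=(1.0, 1.0),
        transfer_intercept=(0.0, 0.0),
        drift_amplitude=(0.0, 0.0),
        nl_slope48=0.0,
        noise_sd_d47=0.0,
        noise_sd_d48=0.0,
        noise_sd_d49=0.0,
        noise_sd_d13c=0.0,
        noise_sd_d18o=0.0,
    )


@pytest.fixture
def distorted_quiet_config():
    """Default distortions but zero noise and zero drift (exact recovery)."""
    return SimulationConfig(
        drift_amplitude=(0.0, 0.0),
        noise_sd_d47=0.0,
        noise_sd_d48=0.0,
        noise_sd_d49=0.0,
        noise_sd_d13c=0.0,
        noise_sd_d18o=0.0,
    )
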