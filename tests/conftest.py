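import numpy as np
import pytest

from carvemetrics.synthetic_data import SimConfig


@pytest.fixture(scope="session")
def noise_free_config() -> SimConfig:
    """Generator settings with every stochastic term switched off."""
    return SimConfig(
        peak_turn_sd=0.0, rfd_turn_sd=0.0, ttp_turn_sd=0.0, uphill_turn_sd=0.0,
        force_noise_sd=0.0, subject_sd_intercept=0.0, subject_sd_slope=0.0,
        rfd_subject_sd=0.0, uphill_subject_sd=0.0, gyro_noise_sd=0.0,
        gyro_bias_sd=0.0, edge_angle_turn_sd=0.0,
        dorsal_subject_sd=0.0, plantar_subject_sd=0.0,
        dorsal_frame_noise_sd=0.0, plantar_frame_noise_sd=0.0,
        n_static_frames=2,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
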