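import numpy as np
import pytest

from gaitsynth import (
    GaitParameters,
    build_upperleg_layout,
    default_body,
    simulate_gait,
)


@pytest.fixture(scope="session")
def body():
    return default_body()


@pytest.fixture(scope="session")
def athlete_params():
    """Noiseless, perfectly periodic treadmill running at 2 m/s."""
    return GaitParameters(speed_mps=2.0, mean_stride_ms=814.6, stride_sd_ms=0.0, seed=1)


@pytest.fixture(scope="session")
def athlete_motion(body, athlete_params):
    return simulate_gait(body, athlete_params, 8)


@pytest.fixture(scope="session")
def upperleg_layout():
    return build_upperleg_layout()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
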