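import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pupilpress import (
    NoiseConfig,
    ProtocolConfig,
    PupilResponseParams,
    SceneConfig,
    simulate_area_series,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def protocol():
    return ProtocolConfig()


@pytest.fixture
def params():
    return PupilResponseParams()


@pytest.fixture
def noiseless_series(params, protocol):
    """Noiseless recording at the reference IOP (tau_d = tau_ref = 2 s)."""
    return simulate_area_series(params, params.iop_ref, protocol, NoiseConfig())


@pytest.fixture
def small_scene():
    """Reduced frame size to keep imaging tests quick."""
    return SceneConfig(frame_px=(160, 200))
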