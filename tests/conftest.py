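import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from scorploc import (
    ChannelMismatch,
    ModelConfig,
    SineWaveform,
    SourceTrajectory,
    make_geometry,
    render_scene,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometry8():
    return make_geometry(8, 0.09, 343.0)


@pytest.fixture(scope="session")
def clean_static_scene(geometry8):
    """1 s clean (no noise, matched channels) 1 kHz sine from bearing 0."""
    traj = SourceTrajectory(kind="static", start_bearing_deg=0.0, duration_s=1.0)
    return render_scene(
        geometry8, traj, SineWaveform(frequency=1000.0), ChannelMismatch.ideal(8), seed=0
    )


@pytest.fixture()
def deterministic_model():
    """Model with the sensory noise switched off (exact symmetry regime)."""
    return ModelConfig(sensory_noise_sigma=0.0)
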