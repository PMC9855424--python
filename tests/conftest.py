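import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def paced_trace():
    """Noiseless 0.5 Hz paced trace at 50 Hz (the field-stimulation protocol)."""
    from cardiopheno.synthetic import make_calcium_trace

    return make_calcium_trace(
        duration_s=60.0, fs_hz=50.0, mode="paced", interval_s=2.0,
        interval_jitter_sd_s=0.0, ttp_s=0.2, tau_s=0.4, amplitude=1.0, diastolic=1.0,
    )


@pytest.fixture
def h_layout():
    """Two verticals joined by a crossbar: one network with two junctions."""
    return [((10, 10), (40, 10)), ((10, 40), (40, 40)), ((25, 10), (25, 40))]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
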