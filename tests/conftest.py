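import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def kp_profile():
    """Noiseless Korsmeyer–Peppas curve (k = 0.0591, n = 0.6219) on days 1..30."""
    from releasekin import ReleaseProfile

    t = np.arange(1.0, 31.0)
    return ReleaseProfile(t, 0.0591 * t**0.6219, sample_label="kp_noiseless")


@pytest.fixture()
def two_phase_times():
    """40 evenly spaced sampling days on (0, 14] containing the changepoint t = 5."""
    return tuple(np.linspace(0.5, 14.0, 40))
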