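import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def straight_axon():
    """Straight 1.5 mm axon over a sparse 15-electrode line; the proximal
    electrode carries the large AIS-like signal."""
    from axontrack.presets import kinetics_preset

    return kinetics_preset()
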