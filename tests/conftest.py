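import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from retseg.synthetic import SynthSpec, generate_fundus  # noqa: E402


@pytest.fixture(scope="session")
def synth_small():
    """One 128x128 synthetic fundus image with mask and truth."""
    return generate_fundus(SynthSpec(height=128, width=128, seed=11))


@pytest.fixture(scope="session")
def synth_small_pair():
    """Two 128x128 synthetic images (distinct seeds)."""
    return [
        generate_fundus(SynthSpec(height=128, width=128, seed=s)) for s in (11, 12)
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
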