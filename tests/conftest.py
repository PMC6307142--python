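import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from riboquad import synth

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_sim():
    """A mid-size synthetic dataset under the default study conditions."""
    return synth.simulate(synth.SimConfig(n_transcripts=60, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
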