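import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from gcfn.dataio import TrialSet
from gcfn.synth import SynthConfig, generate


@pytest.fixture(scope="session")
def small_trialset() -> TrialSet:
    """24 synthetic trials (6/class), full 22 x 875 geometry."""
    return generate(SynthConfig(n_per_class=6, seed=5))


@pytest.fixture(scope="session")
def erd_trialset() -> TrialSet:
    """200 trials (50/class) with pronounced ERD, for band-power checks."""
    return generate(SynthConfig(n_per_class=50, erd_depth=0.5, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
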