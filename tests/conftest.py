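import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seedling_observer import default_effect_model, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """One 73-sample dataset from the packaged design, seed 0."""
    return generate_dataset(effects=default_effect_model(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
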