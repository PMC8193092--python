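import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from intercrop import synthetic

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def design():
    return synthetic.default_design()


@pytest.fixture(scope="session")
def truth():
    return synthetic.default_truth()


@pytest.fixture(scope="session")
def noiseless_dataset(design, truth):
    """Full-design harvest table with zero noise: fits must recover truth."""
    noise = synthetic.NoiseSpec(cv_or_sd=0.0, seed=0, delta15n_sd=0.0)
    return synthetic.generate_experiment(design, truth, noise)


@pytest.fixture(scope="session")
def noisy_dataset(design, truth):
    """Default study conditions: multiplicative log-normal noise, CV 10%."""
    noise = synthetic.NoiseSpec(cv_or_sd=0.10, seed=1)
    return synthetic.generate_experiment(design, truth, noise)


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)
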