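import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from reefdemo.inference_core import MCMCConfig
from reefdemo.synthetic_data import SyntheticConfig, simulate_fish

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fast_mcmc() -> MCMCConfig:
    """Reduced-draw sampler settings for unit tests."""
    return MCMCConfig(chains=2, iterations=600, warmup=200, seed=11)


@pytest.fixture(scope="session")
def study_fish():
    """One synthetic fish collection at study-like scale (8 islands x 15 fish)."""
    return simulate_fish(SyntheticConfig(n_atolls=4, seed=42))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
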