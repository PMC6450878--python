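import pytest
from hypothesis import HealthCheck, settings

from optiquant.simulate import SimulationParams, simulate_field

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

NOISE_FREE = dict(psf_sigma=0.0, poisson_noise=False, gaussian_read_sd=0.0)


@pytest.fixture(scope="session")
def noise_free_params() -> SimulationParams:
    return SimulationParams(seed=1, **NOISE_FREE)


@pytest.fixture(scope="session")
def noise_free_field(noise_free_params):
    return simulate_field(noise_free_params)


@pytest.fixture(scope="session")
def default_field():
    """One field at the default (blur + noise) settings."""
    return simulate_field(SimulationParams(seed=42))
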