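import pytest
from hypothesis import HealthCheck, settings

from vestibattery.cohort import generate_cohort, load_default_params

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    return load_default_params()


@pytest.fixture(scope="session")
def cohort(default_params):
    """One study-sized synthetic cohort (231 patients, fixed seed)."""
    return generate_cohort(default_params, seed=1)


@pytest.fixture(scope="session")
def fifty_cohorts(default_params):
    """Fifty study-sized cohorts for the simulation-based checks."""
    return [generate_cohort(default_params, seed=s) for s in range(50)]
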