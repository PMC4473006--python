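import pytest
from hypothesis import HealthCheck, settings

from ostai import generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A 2,000-woman study-like cohort (seeded) shared across tests."""
    cohort, truth = generate_cohort(n=2000, seed=7)
    return cohort, truth


@pytest.fixture(scope="session")
def study_cohort():
    """A 20,000-woman cohort at the scale used for derivation tests."""
    cohort, truth = generate_cohort(n=20000, seed=11)
    return cohort, truth
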