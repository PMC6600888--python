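import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def catalog():
    from grogscreen import default_catalog

    return default_catalog()


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 60-person cohort shared by I/O and pipeline tests."""
    from grogscreen import CohortParams, generate_cohort

    return generate_cohort(CohortParams(n_participants=60), seed=11)
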