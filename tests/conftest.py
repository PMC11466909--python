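import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=40,
    suppress_health_check=list(HealthCheck), deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def trimolecular_census():
    from crnbif.enumeration import census, spec_trimolecular_distinct
    return census(spec_trimolecular_distinct())


@pytest.fixture(scope="session")
def bimolecular_census():
    from crnbif.enumeration import census, spec_bimolecular_distinct
    return census(spec_bimolecular_distinct())


@pytest.fixture(scope="session")
def hopf_base_census():
    from crnbif.enumeration import census, spec_hopf_base
    return census(spec_hopf_base())


@pytest.fixture(scope="session")
def full_report():
    """The complete classification pipeline, run once per session."""
    from crnbif.pipeline import run_census
    return run_census()
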