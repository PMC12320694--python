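import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_config():
    from lymphoti.synthetic import GeneratorConfig

    return GeneratorConfig()


@pytest.fixture(scope="session")
def default_cohort(default_config):
    """One default 45-patient cohort, shared across tests."""
    from lymphoti.synthetic import generate_cohort

    return generate_cohort(default_config, seed=11)


@pytest.fixture()
def cohort_dir(tmp_path, default_cohort):
    """The default cohort written out as reads/volumetry/patients CSVs."""
    from lymphoti.synthetic import write_cohort

    return write_cohort(default_cohort, tmp_path / "cohort")
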