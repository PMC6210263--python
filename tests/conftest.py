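import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry():
    from workrisk import load_default_registry

    return load_default_registry()


@pytest.fixture(scope="session")
def case_study_records():
    from workrisk import case_study_fixture

    return case_study_fixture()
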