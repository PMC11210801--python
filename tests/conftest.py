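import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def reference_records():
    from lowriskec.fixtures import reference_cohort

    return reference_cohort()


@pytest.fixture(scope="session")
def reference_tab(reference_records):
    from lowriskec.concordance import crosstab

    return crosstab(reference_records)
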