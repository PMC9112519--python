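import pytest

from pmslt import packaged_cohort_inputs, packaged_risk_functions, ScenarioConfig


@pytest.fixture(scope="session")
def table2():
    return packaged_cohort_inputs()


@pytest.fixture(scope="session")
def risks():
    return packaged_risk_functions()


@pytest.fixture()
def cfg():
    return ScenarioConfig()
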