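import pytest

from prepcost import (
    Arm,
    PrEPDeliveryCostModel,
    load_fixture_accruals,
    load_fixture_ledger,
)


@pytest.fixture(scope="session")
def trial_ledger():
    return load_fixture_ledger("trial")


@pytest.fixture(scope="session")
def moh_ledger():
    return load_fixture_ledger("moh")


@pytest.fixture(scope="session")
def accruals():
    return load_fixture_accruals()


@pytest.fixture(scope="session")
def trial_results():
    return PrEPDeliveryCostModel.from_fixture("trial").fit()


@pytest.fixture(scope="session")
def moh_results():
    return PrEPDeliveryCostModel.from_fixture("moh").fit()


@pytest.fixture(scope="session")
def moh_creatinine_results():
    return PrEPDeliveryCostModel.from_fixture("moh_creatinine").fit()


@pytest.fixture(scope="session")
def soc_accrual(accruals):
    return accruals[Arm.soc]


@pytest.fixture(scope="session")
def intervention_accrual(accruals):
    return accruals[Arm.intervention]
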