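import pytest

from pahcea import (CohortSpec, EconSettings, MarkovCEA,
                    default_life_table, default_parameter_set)


@pytest.fixture(scope="session")
def params():
    return default_parameter_set()


@pytest.fixture(scope="session")
def cohort():
    return CohortSpec()


@pytest.fixture(scope="session")
def settings():
    return EconSettings()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def model(params, cohort, settings, life_table):
    return MarkovCEA(params, cohort, settings, life_table)


@pytest.fixture(scope="session")
def fitted(model):
    """Base-case results on the synthetic life table, shared across tests."""
    return model.fit()
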