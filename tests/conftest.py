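import pytest

from pdregio import (
    PredictorConfig,
    TabulatedBackend,
    load_paper_fixtures,
    parse_substrate,
)


@pytest.fixture(scope="session")
def fixture_set():
    return load_paper_fixtures()


@pytest.fixture(scope="session")
def tabulated_backend(fixture_set):
    return TabulatedBackend(table=fixture_set.energy_table)


@pytest.fixture(scope="session")
def default_cfg():
    return PredictorConfig()


@pytest.fixture()
def benzene():
    return parse_substrate("c1ccccc1", "benzene")


@pytest.fixture()
def indole():
    return parse_substrate("c1ccc2[nH]ccc2c1", "indole")
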