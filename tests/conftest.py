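import pytest

from norscba import OverdoseMonitoringCBA, load_parameters, nors_fixture, tally


@pytest.fixture(scope="session")
def nors_params():
    return load_parameters("nors2022")


@pytest.fixture(scope="session")
def fixture_records():
    return nors_fixture()


@pytest.fixture(scope="session")
def fixture_tallies(fixture_records):
    return tally(fixture_records)


@pytest.fixture(scope="session")
def fitted():
    return OverdoseMonitoringCBA.from_fixture().fit()
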