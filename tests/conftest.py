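import pytest

from dcmvus import EngineConfig, load_fixture, reclassify_all


@pytest.fixture(scope="session")
def config():
    return EngineConfig()


@pytest.fixture(scope="session")
def fixture_with_expected():
    records, expected = load_fixture(with_expected=True)
    return records, expected


@pytest.fixture(scope="session")
def fixture_records(fixture_with_expected):
    return fixture_with_expected[0]


@pytest.fixture(scope="session")
def classified_fixture(fixture_records, config):
    return reclassify_all(fixture_records, config)
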