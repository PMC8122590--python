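import pytest

from tfcensus.classifier import default_rules
from tfcensus.io_formats import load_paper_fixtures


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def fixtures():
    return load_paper_fixtures()


@pytest.fixture(scope="session")
def table1(fixtures):
    return fixtures.table1
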