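import pytest

from evsmallrna.adapters import AdapterPattern
from evsmallrna.catalog import default_catalog, generate_catalog
from evsmallrna.simulate import DEFAULT_ADAPTER3


@pytest.fixture(scope="session")
def catalog():
    """Full host + nonhost catalog shared across tests (read-only)."""
    return default_catalog(1)


@pytest.fixture(scope="session")
def mirna_catalog():
    """miRNA-only catalog for adapter-anchor tests."""
    return generate_catalog(2, {"miRNA": 30})


@pytest.fixture(scope="session")
def truseq_pattern():
    return AdapterPattern(DEFAULT_ADAPTER3, rand5_len=4, rand3_len=4)
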