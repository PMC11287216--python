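import pytest

from sedguilds.catalog import default_catalog


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def marker_vocab(catalog):
    return sorted(catalog.markers)
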