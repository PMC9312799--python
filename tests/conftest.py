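import pytest

from solbinder import aaindex


@pytest.fixture(scope="session")
def oriented_tables():
    """The three bundled indices, normalized and loss-oriented."""
    return {name: aaindex.oriented_index(name) for name in aaindex.BUNDLED_INDICES}


@pytest.fixture(scope="session")
def hydropathy(oriented_tables):
    return oriented_tables["hydropathy"]
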