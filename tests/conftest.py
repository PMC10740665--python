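import pytest

from mabvisc import DEFAULT_PARAMS
from mabvisc.data_io import load_test_panel, load_validation_panel


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def validation_panel():
    """17-molecule validation panel bundled with the package."""
    return load_validation_panel()


@pytest.fixture(scope="session")
def test_panel():
    """9-molecule test panel bundled with the package."""
    return load_test_panel()
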