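import pytest

from mihakit import load_reference_panel
from mihakit.simulate import DEFAULT_SEED


@pytest.fixture(scope="session")
def reference_panel():
    """The shipped ten-MiHA monitoring kit panel (5 fluorochromes, 10 codes)."""
    return load_reference_panel()


@pytest.fixture(scope="session")
def base_seed():
    return DEFAULT_SEED
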