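import pytest

from bnpcea.params import default_bundle


@pytest.fixture
def bundle():
    return default_bundle()


@pytest.fixture
def short_bundle():
    """Default inputs but a 5-year horizon — fast runs for structural tests."""
    b = default_bundle()
    b.config.horizon_years = 5.0
    return b
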