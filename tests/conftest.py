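import pytest

from htncea.params import default_parameters


@pytest.fixture()
def params():
    """Fresh default parameter book per test (mutable without leakage)."""
    return default_parameters()
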