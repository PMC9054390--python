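import pytest

from rbfqsar import SyntheticSpec, generate


@pytest.fixture(scope="session")
def default_table():
    """The reference synthetic scenario (one fixed seed)."""
    return generate(SyntheticSpec(seed=11))
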