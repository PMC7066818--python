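import pytest

from healthecon import generate_synthetic_pack


@pytest.fixture(scope="session")
def pack():
    """One validated synthetic parameter pack shared across the suite."""
    return generate_synthetic_pack(seed=1)
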