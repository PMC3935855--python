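import pytest

from enosesim import generate_profile_bank


@pytest.fixture(scope="session")
def bank():
    """The default synthetic prototype bank (seed 0)."""
    return generate_profile_bank(0)
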