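import random

import pytest

from curveball import fixtures


@pytest.fixture
def rng():
    return random.Random(12345)


@pytest.fixture(scope="session")
def bank():
    return fixtures()
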