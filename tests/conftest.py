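import pytest

from mpphap import AlphaDistribution, example_alpha, hs_alpha


@pytest.fixture
def hs():
    return hs_alpha()


@pytest.fixture
def do_alpha():
    return example_alpha()


@pytest.fixture
def skewed_alpha():
    return AlphaDistribution({2: 0.5, 3: 0.3, 5: 0.2})
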