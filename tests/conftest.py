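import pytest

from phstrain import get_scenario


@pytest.fixture(scope="session")
def nc4():
    return get_scenario("NC-4")


@pytest.fixture(scope="session")
def sc2():
    return get_scenario("SC-2")


@pytest.fixture(scope="session")
def lc():
    return get_scenario("LC")
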