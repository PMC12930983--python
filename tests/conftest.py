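import pytest

from oxidogem import synth
from oxidogem.synth import ToyModelSpec, build_toy_model


@pytest.fixture(scope="session")
def toy_model():
    return build_toy_model()


@pytest.fixture(scope="session")
def markers():
    return synth.toy_markers()


@pytest.fixture(scope="session")
def free_media():
    return ("EX_o2", "EX_nh4", "EX_pi", "EX_h2o", "EX_h")


@pytest.fixture(scope="session")
def energetics_map():
    return synth.toy_energetics_map()


@pytest.fixture(scope="session")
def biomass_map():
    return synth.toy_biomass_map()
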