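import pytest

from bayesgaze.scenario import load_packaged_scenario
from bayesgaze.strategies import ClassifierConfig


@pytest.fixture(scope="session")
def mammography():
    return load_packaged_scenario("mammography")


@pytest.fixture(scope="session")
def economics():
    return load_packaged_scenario("economics")


@pytest.fixture(scope="session")
def scenarios(mammography, economics):
    return {"mammography": mammography, "economics": economics}


@pytest.fixture
def cfg():
    return ClassifierConfig()
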