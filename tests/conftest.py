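import pytest
from hypothesis import settings

from boolkit.compiler import build_update_rules
from boolkit.nlrp3 import load_nlrp3_network, run_catalogue
from boolkit.sim import natural_off_state

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def nlrp3_kb():
    return load_nlrp3_network()


@pytest.fixture(scope="session")
def nlrp3_model(nlrp3_kb):
    return build_update_rules(nlrp3_kb)


@pytest.fixture(scope="session")
def nlrp3_off(nlrp3_model):
    return natural_off_state(nlrp3_model)


@pytest.fixture(scope="session")
def catalogue(nlrp3_kb):
    """name -> (scenario, result, activation call) for the whole catalogue."""
    return {sc.name: (sc, res, call) for sc, res, call in run_catalogue(nlrp3_kb)}
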