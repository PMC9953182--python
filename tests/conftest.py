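import pytest

from lymphnet.model import load_model
from lymphnet.invariants import place_invariants, transition_invariants
from lymphnet.manatee import manatee_invariants
from lymphnet.pbopn import delete_antibody_production, to_pbopn


@pytest.fixture(scope="session")
def model():
    return load_model()


@pytest.fixture(scope="session")
def model_tis(model):
    return transition_invariants(model)


@pytest.fixture(scope="session")
def model_pis(model):
    return place_invariants(model)


@pytest.fixture(scope="session")
def model_pbopn(model):
    reduced, record = to_pbopn(model)
    return reduced, record


@pytest.fixture(scope="session")
def model_pbopn_pis(model_pbopn):
    return place_invariants(model_pbopn[0])


@pytest.fixture(scope="session")
def model_ab_deleted(model_pbopn):
    return delete_antibody_production(model_pbopn[0])


@pytest.fixture(scope="session")
def model_mis(model, model_tis, model_pis):
    return manatee_invariants(model, model_tis, model_pis)
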