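import pytest

from metaflex.model_fixtures import (
    base_parameterization,
    metabolic_flexibility_network,
    pdk_variants,
    toy_model,
)


@pytest.fixture(scope="session")
def toy():
    """(network, Table-style parameterization) of the three-entity example."""
    return toy_model()


@pytest.fixture(scope="session")
def full_net():
    return metabolic_flexibility_network()


@pytest.fixture(scope="session")
def variants():
    return pdk_variants()


@pytest.fixture(scope="session")
def full_params(full_net, variants):
    """Parameterizations of the full model keyed by variant id."""
    return {v.id: base_parameterization(v, full_net) for v in variants}
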