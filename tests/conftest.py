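import numpy as np
import pytest

import colonsim as cs


@pytest.fixture(scope="session")
def params():
    return cs.default_parameters()


@pytest.fixture(scope="session")
def layout():
    return cs.build_state_layout()


@pytest.fixture(scope="session")
def network(layout, params):
    return cs.build_reaction_network(layout, params)


def transport_only_params():
    """A parameter set with all reaction and exchange processes switched off."""
    p = cs.default_parameters()
    p.hydrolysis.k_hyd = 0.0
    for g in cs.BFGS:
        p.groups[g].k_m = 0.0
        p.groups[g].k_dec = 0.0
    p.exchange.absorb = {k: 0.0 for k in p.exchange.absorb}
    p.exchange.attach = 0.0
    p.exchange.detach = 0.0
    p.exchange.sugar_diffusion = 0.0
    p.exchange.mucus_production = 0.0
    p.exchange.slough = 0.0
    p.initial.biomass_seed = 0.0
    return p


@pytest.fixture()
def transport_params():
    return transport_only_params()
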