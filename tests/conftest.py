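import numpy as np
import pytest

from mucosim import (GEMModel, Reaction, make_consumer, make_producer,
                     make_toy_chain)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_chain():
    """3-reaction chain: uptake 10, biomass yield 0.5 -> mu* = 5."""
    return make_toy_chain()


@pytest.fixture
def producer():
    return make_producer()


@pytest.fixture
def consumer():
    return make_consumer()


@pytest.fixture
def redundant_routes():
    """Two glucose -> acetate routes (1 vs 3 internal reactions), objective =
    acetate export; both attain the optimum, parsimony picks the short one."""
    mets = ["glc", "i1", "i2", "ac"]
    rxns = [
        Reaction("EX_glc", {"glc": -1.0}, -10.0, 0.0),
        Reaction("SHORT", {"glc": -1.0, "ac": 1.0}, 0.0, 1000.0),
        Reaction("LONG1", {"glc": -1.0, "i1": 1.0}, 0.0, 1000.0),
        Reaction("LONG2", {"i1": -1.0, "i2": 1.0}, 0.0, 1000.0),
        Reaction("LONG3", {"i2": -1.0, "ac": 1.0}, 0.0, 1000.0),
        Reaction("EX_ac", {"ac": -1.0}, 0.0, 1000.0),
    ]
    return GEMModel("redundant", mets, rxns, "EX_ac",
                    {"EX_glc": "glucose", "EX_ac": "acetate"})
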