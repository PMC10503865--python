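import numpy as np
import pytest

from cometab.core import Metabolite, Reaction, StoichiometricModel
from cometab.synthetic import (
    ToyHostSpec,
    host_base_diet,
    make_cometabolism_fixture,
    make_toy_host,
    make_toy_microbe,
)


@pytest.fixture
def chain_model():
    """a -> b with exchanges; max EX_b is min(uptake limit, conversion cap)."""
    m = StoichiometricModel(id="chain")
    m.add_metabolite(Metabolite("a[c]"))
    m.add_metabolite(Metabolite("b[c]"))
    m.add_reaction(Reaction("EX_a", {"a[c]": -1.0}, -10.0, 1000.0))
    m.add_reaction(Reaction("CONV", {"a[c]": -1.0, "b[c]": 1.0}, 0.0, 6.0))
    m.add_reaction(Reaction("EX_b", {"b[c]": -1.0}, 0.0, 1000.0))
    m.objective = "EX_b"
    return m


@pytest.fixture
def toy_host():
    return make_toy_host(ToyHostSpec(sex="male"))


@pytest.fixture
def screen_diet():
    return host_base_diet()


@pytest.fixture
def cometabolism_fixture():
    return make_cometabolism_fixture()


@pytest.fixture
def simple_microbe():
    return make_toy_microbe("M", formate_rate=3.0, precursors={"prec": 4.0})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
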