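import pytest

from nodulefba.assembly import HolobiontSpec, build_holobiont
from nodulefba.toy import ToyConfig, generate_toy_holobiont_inputs

#: the toy holobiont's constant-efficiency operating point (umol N2 h^-1 per g
#: nodule DW), near its Pareto optimum -- the miniature system's analogue of
#: the full-scale 150
TOY_EFFICIENCY = 100.0


@pytest.fixture(scope="session")
def toy_config():
    return ToyConfig()


@pytest.fixture(scope="session")
def toy_inputs(toy_config):
    return generate_toy_holobiont_inputs(toy_config)


@pytest.fixture(scope="session")
def plant(toy_inputs):
    return toy_inputs[0]


@pytest.fixture(scope="session")
def bacterium(toy_inputs):
    return toy_inputs[1]


@pytest.fixture(scope="session")
def calls(toy_inputs):
    return toy_inputs[2]


@pytest.fixture(scope="session")
def holobiont_session(toy_inputs):
    """Default gated, pruned, N2-only holobiont (shared; do not mutate)."""
    plant, bacterium, calls = toy_inputs
    return build_holobiont(plant, bacterium, HolobiontSpec(), calls)


@pytest.fixture
def holobiont(holobiont_session):
    """Mutable copy of the default holobiont."""
    return holobiont_session.copy()


@pytest.fixture(scope="session")
def sucrose_variant_holobiont():
    """Holobiont whose zone III bacteroids may also import sucrose."""
    cfg = ToyConfig(include_sucrose_bacteroid_path=True)
    plant, bacterium, calls = generate_toy_holobiont_inputs(cfg)
    spec = HolobiontSpec(sucrose_bacteroid_variant=True)
    return build_holobiont(plant, bacterium, spec, calls)
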