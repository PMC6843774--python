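import pytest

from diatomkey import load_bundled_key, load_bundled_species
from diatomkey.model import (
    Chart,
    CharacterDef,
    DecisionNode,
    EdgeTarget,
    FlowChart,
    Interval,
    SpeciesDB,
    SpeciesRecord,
)


@pytest.fixture(scope="session")
def key():
    return load_bundled_key()


@pytest.fixture(scope="session")
def db():
    return load_bundled_species()


def make_linear_key():
    """Two-question single-chart key with one species leaf."""
    char = CharacterDef("shape", "valve shape", states=("round", "long", "odd"))
    nodes = [
        DecisionNode("n1", "K1", "shape", "first?",
                     {"round": EdgeTarget.node("n2")}),
        DecisionNode("n2", "K1", "shape", "second?",
                     {"round": EdgeTarget.species("only_one")}),
    ]
    key = FlowChart.build([char], [Chart("K1", "toy", "n1")], nodes, "K1")
    db = SpeciesDB.build([
        SpeciesRecord("only_one", "Only one", "Only",
                      length_range_um=Interval(10, 20),
                      width_range_um=Interval(2, 4)),
    ])
    return key, db


@pytest.fixture()
def linear_key():
    return make_linear_key()
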