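import pytest

from crustbio import energetics as en
from crustbio import markers as mk


@pytest.fixture(scope="session")
def species_table():
    return en.load_species_table()


@pytest.fixture(scope="session")
def reactions():
    return en.load_reactions()


@pytest.fixture(scope="session")
def jdfr():
    return en.load_conditions("jdfr")


@pytest.fixture(scope="session")
def marker_sets():
    return mk.load_marker_sets()


@pytest.fixture
def toy_species():
    """A and B: isomers (same composition) differing only in formation props."""
    return {
        "A": en.Species("A", {"X": 1}, 0, dGf0=0.0, dHf0=5.0),
        "B": en.Species("B", {"X": 1}, 0, dGf0=-10.0, dHf0=5.0),
    }


@pytest.fixture
def toy_reaction():
    return en.Reaction("a_to_b", {"A": -1, "B": 1}, n_electrons=1,
                       donor="A", acceptor="A")
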