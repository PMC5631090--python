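import pytest

from otubench import simulate
from otubench.pipeline import generate_fixtures
from otubench.tags import Primer, PrimerPair


@pytest.fixture(scope="session")
def fixtures():
    """Deterministic small-community bundle shared across tests."""
    return generate_fixtures(seed=0)


@pytest.fixture(scope="session")
def primer_pairs():
    return simulate.default_primer_pairs()


@pytest.fixture
def toy_pair():
    """A short exact primer pair for constructed-amplicon tests."""
    return PrimerPair(
        "toy",
        Primer("toyF", "GTGCCAGC", "forward"),
        Primer("toyR", "GGATTAGA", "reverse"),
        max_mismatches=2,
    )
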