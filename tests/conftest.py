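import numpy as np
import pandas as pd
import pytest

from nicomm.markers import default_marker_catalog
from nicomm.pathways import default_pathway_definitions
from nicomm.synthetic import generate_community


@pytest.fixture(scope="session")
def catalog():
    return default_marker_catalog()


@pytest.fixture(scope="session")
def pathway_defs():
    return default_pathway_definitions()


@pytest.fixture(scope="session")
def small_bundle():
    """A small null community (no planted effects) with bins and env table."""
    return generate_community(n_species=8, seed=1)


@pytest.fixture(scope="session")
def effect_bundle():
    """A community with planted up- and down-effects."""
    return generate_community(
        n_species=12,
        seed=3,
        effect_spec={"S01": 8.0, "S03": 8.0, "S05": 0.125, "S07": 0.125},
    )


def mutate_with(ref: str, positions, table=None) -> str:
    """Deterministically substitute given positions of a sequence."""
    table = table or {"A": "C", "C": "G", "G": "T", "T": "A"}
    s = list(ref)
    for p in positions:
        s[p] = table[s[p]]
    return "".join(s)


@pytest.fixture(scope="session")
def random_dna():
    rng = np.random.default_rng(11)
    bases = np.array(list("ACGT"))

    def make(n: int) -> str:
        return "".join(bases[rng.integers(0, 4, n)])

    return make
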