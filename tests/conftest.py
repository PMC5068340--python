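import pytest

from larvid.synthdata import SynthConfig, simulate
from larvid.taxonomy import Lineage, Taxonomy


@pytest.fixture(scope="session")
def small_taxonomy() -> Taxonomy:
    """2 orders × 2 families × 2 genera × 2 species = 16 lineages."""
    from larvid.synthdata import generate_taxonomy

    return generate_taxonomy(2, 2, 2, 2, seed=1)


@pytest.fixture(scope="session")
def clean_sim():
    """Complete, concordant, duplicate-free databases; low divergence."""
    return simulate(SynthConfig(n_species=12, n_queries=40, divergence=0.005, seed=3))


@pytest.fixture
def toy_lineages():
    return {
        "A": Lineage("Ord1", "Fam1", "GenA", "GenA sp1"),
        "B": Lineage("Ord1", "Fam1", "GenA", "GenA sp2"),
        "C": Lineage("Ord1", "Fam1", "GenB", "GenB sp1"),
        "D": Lineage("Ord1", "Fam2", "GenC", "GenC sp1"),
        "E": Lineage("Ord2", "Fam3", "GenD", "GenD sp1"),
    }
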