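import pytest

from phylophase.io import TaxonomyMap, read_gene_tree
from phylophase.simulate import SimulationConfig, simulate_phylome


def make_taxonomy(genes: dict[str, tuple[str, str]]) -> TaxonomyMap:
    """Build a TaxonomyMap from {gene_id: (species, section)}."""
    g2s = {g: sp for g, (sp, _) in genes.items()}
    s2c = {}
    for sp, sec in genes.values():
        s2c[sp] = sec
    return TaxonomyMap(g2s, s2c)


@pytest.fixture
def toy_taxonomy() -> TaxonomyMap:
    return make_taxonomy({
        "seed": ("benthamiana", "Suaveolentes"),
        "seedParalog": ("benthamiana", "Suaveolentes"),
        "noc1": ("noctiflora", "Noctiflorae"),
        "noc2": ("noctiflora", "Noctiflorae"),
        "syl1": ("sylvestris", "Sylvestres"),
        "pet1": ("attenuata", "Petunioides"),
        "tom1": ("tomentosiformis", "Tomentosae"),
    })


@pytest.fixture
def four_leaf_tree(toy_taxonomy):
    """Worked example: seed with one Noctiflorae sister and a
    Sylvestres/Petunioides outgroup clade."""
    return read_gene_tree(
        "((seed:0.01,noc1:0.02)0.95:0.005,(syl1:0.03,pet1:0.04)0.90:0.01);",
        toy_taxonomy, seed_gene="seed", tree_id="t1")


@pytest.fixture(scope="session")
def small_synth():
    """A 300-gene synthetic phylome shared (read-only) across tests."""
    return simulate_phylome(SimulationConfig(n_genes=300, rng_seed=11))
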