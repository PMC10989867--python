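import dataclasses

import pytest

from markersieve import (
    SimulationConfig,
    clades_from_taxonomy,
    simulate_gene_trees,
    simulate_species_tree,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        n_clades_A=2,
        n_clades_B=2,
        taxa_per_clade=3,
        n_outgroup=2,
        focal_size=2,
        n_markers=30,
        hgt_rate=0.4,
        contaminant_rate=0.1,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """A small simulated study: species tree, taxonomy, gene trees, truth."""
    species, taxmap = simulate_species_tree(small_cfg)
    trees, truth = simulate_gene_trees(species, taxmap, small_cfg)
    return {
        "cfg": small_cfg,
        "species": species,
        "taxmap": taxmap,
        "trees": trees,
        "truth": truth,
        "clades": clades_from_taxonomy(taxmap),
        "groupsA": ["A1", "A2"],
        "groupsB": ["B1", "B2"],
    }


@pytest.fixture()
def replace_cfg(small_cfg):
    def _replace(**kw):
        return dataclasses.replace(small_cfg, **kw)

    return _replace
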