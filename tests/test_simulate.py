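"""Generator ground truth: determinism, event bookkeeping, divergence."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from markersieve import (
    Monophyly,
    SimulationConfig,
    clades_from_taxonomy,
    evolve_alignment,
    is_monophyletic,
    read_newick,
    simulate_gene_trees,
    simulate_species_tree,
)
from markersieve.simulate import write_dataset


class TestSpeciesTree:
    def test_minimal_config_shape(self):
        cfg = SimulationConfig(
            n_clades_A=1, n_clades_B=1, taxa_per_clade=2, n_outgroup=1,
            focal_size=2, n_markers=1, seed=0,
        )
        tree, taxmap = simulate_species_tree(cfg)
        assert len(tree.leaf_ids) == 7
        focal = taxmap.genomes_with_role("focal")
        assert len(focal) == 2
        from markersieve import CladeDefinition

        assert is_monophyletic(tree, CladeDefinition("FOCAL", focal)) is Monophyly.MONOPHYLETIC

    def test_same_seed_identical_newick(self, small_cfg):
        t1, _ = simulate_species_tree(small_cfg)
        t2, _ = simulate_species_tree(small_cfg)
        assert t1.to_newick() == t2.to_newick()

    def test_all_clades_monophyletic(self, small_world):
        for clade in small_world["clades"]:
            assert is_monophyletic(small_world["species"], clade) is Monophyly.MONOPHYLETIC

    def test_taxonomy_consistent_with_tree(self, small_world):
        assert set(small_world["species"].leaf_ids) == set(
            small_world["taxmap"].genome_ids
        )

    @pytest.mark.parametrize("field,value", [
        ("n_markers", 0), ("hgt_rate", 1.5), ("contaminant_rate", -0.1),
        ("graft_target", "C"),
    ])
    def test_config_validation(self, field, value):
        with pytest.raises(ValueError):
            SimulationConfig(**{field: value})


class TestGeneTrees:
    def test_no_events_means_identical_topology(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, hgt_rate=0.0, contaminant_rate=0.0)
        species, taxmap = simulate_species_tree(cfg)
        trees, truth = simulate_gene_trees(species, taxmap, cfg)
        assert all(t.same_topology(species) for t in trees)
        assert len(truth.clean_ids()) == len(trees)

    def test_forced_grafts_recorded(self, small_cfg):
        cfg = dataclasses.replace(
            small_cfg, hgt_rate=1.0, contaminant_rate=0.0, graft_target="B"
        )
        species, taxmap = simulate_species_tree(cfg)
        _, truth = simulate_gene_trees(species, taxmap, cfg)
        assert all(r.graft_group == "B" for r in truth.records.values())

    def test_graft_fraction_within_binomial_ci(self):
        cfg = SimulationConfig(
            n_clades_A=2, n_clades_B=2, taxa_per_clade=3, n_outgroup=2,
            focal_size=2, n_markers=200, hgt_rate=0.3, contaminant_rate=0.0,
            seed=13,
        )
        species, taxmap = simulate_species_tree(cfg)
        _, truth = simulate_gene_trees(species, taxmap, cfg)
        k = sum(1 for r in truth.records.values() if r.graft_group != "none")
        lo, hi = stats.binom.interval(0.95, 200, 0.3)
        assert lo <= k <= hi

    def test_event_bookkeeping_matches_topology_changes(self, small_world):
        species, trees, truth = (
            small_world["species"], small_world["trees"], small_world["truth"]
        )
        modified = {t.marker_id for t in trees if not t.same_topology(species)}
        nonclean = {m for m, r in truth.records.items() if not r.clean}
        assert modified == nonclean

    def test_leaf_count_preserved_by_events(self, small_world):
        n = len(small_world["species"].leaf_ids)
        assert all(len(t.leaf_ids) == n for t in small_world["trees"])

    def test_graft_plan_length_checked(self, small_cfg):
        species, taxmap = simulate_species_tree(small_cfg)
        with pytest.raises(ValueError):
            simulate_gene_trees(species, taxmap, small_cfg, graft_plan=["A"])

    def test_determinism(self, small_cfg):
        species, taxmap = simulate_species_tree(small_cfg)
        t1, tr1 = simulate_gene_trees(species, taxmap, small_cfg)
        t2, tr2 = simulate_gene_trees(species, taxmap, small_cfg)
        assert [a.to_newick() for a in t1] == [b.to_newick() for b in t2]
        assert tr1.records == tr2.records


class TestEvolveAlignment:
    def test_zero_branch_lengths_give_identical_rows(self):
        star = read_newick("(a:0,b:0,c:0,d:0);", marker_id="m")
        aln = evolve_alignment(star, 100, seed=2)
        assert len(set(aln.rows.values())) == 1

    def test_row_count_and_length(self, small_world):
        aln = evolve_alignment(small_world["trees"][0], 73, seed=9)
        assert len(aln) == len(small_world["trees"][0].leaf_ids)
        assert aln.length == 73

    def test_negative_length_rejected(self, small_world):
        with pytest.raises(ValueError):
            evolve_alignment(small_world["trees"][0], 0, seed=1)

    def test_divergence_monotone_in_path_length(self):
        """Mean pairwise difference grows with branch length (50 replicates)."""
        means = []
        for bl in (0.05, 0.3, 1.0):
            diffs = []
            tree_text = f"(a:{bl},b:{bl});"
            for rep in range(50):
                aln = evolve_alignment(read_newick(tree_text), 200, seed=rep)
                a, b = aln.rows["a"], aln.rows["b"]
                diffs.append(sum(x != y for x, y in zip(a, b)) / 200)
            means.append(np.mean(diffs))
        assert means[0] < means[1] < means[2]


class TestDatasetWriter:
    def test_dataset_write_is_deterministic(self, tmp_path, small_cfg):
        cfg = dataclasses.replace(small_cfg, n_markers=5)
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        write_dataset(d1, cfg)
        write_dataset(d2, cfg)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()
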