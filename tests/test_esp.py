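"""Presence/absence profiles, distances, and hand-rolled UPGMA."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from markersieve import build_matrix, profile_distance, upgma
from markersieve.simulate import SimulationConfig, simulate_esp_hits, simulate_species_tree


def hits_frame(rows):
    return pd.DataFrame(rows, columns=["genome_id", "family_id", "n_copies"])


class TestBuildMatrix:
    def test_empty_hits_all_zero(self):
        m = build_matrix(hits_frame([]), families=["f1", "f2", "f3"],
                         genomes=["g1", "g2"])
        assert m.cells.sum() == 0
        assert m.cells.shape == (2, 3)

    def test_single_hit(self):
        m = build_matrix(hits_frame([("g1", "f2", 1)]), families=["f1", "f2"],
                         genomes=["g1", "g2"])
        assert m.cells.sum() == 1
        assert m.cells[0, 1] == 1

    def test_duplicates_merge_not_error(self):
        m = build_matrix(
            hits_frame([("g1", "f1", 1), ("g1", "f1", 2)]),
            families=["f1"], genomes=["g1"],
        )
        assert m.cells[0, 0] == 1

    def test_row_sums_match_groupby_oracle(self):
        rng = np.random.default_rng(51)
        genomes = [f"g{i}" for i in range(6)]
        fams = [f"f{i}" for i in range(10)]
        rows = []
        for _ in range(60):
            rows.append((
                genomes[rng.integers(6)], fams[rng.integers(10)],
                int(rng.integers(0, 3)),
            ))
        df = hits_frame(rows)
        m = build_matrix(df, families=fams, genomes=genomes)
        oracle = (
            df[df.n_copies > 0].groupby("genome_id")["family_id"].nunique()
        )
        for gi, g in enumerate(genomes):
            assert m.cells[gi].sum() == oracle.get(g, 0)


class TestProfileDistance:
    def test_identical_profiles_zero(self):
        m = build_matrix(hits_frame([("g1", "f1", 1), ("g2", "f1", 1)]),
                         families=["f1"], genomes=["g1", "g2"])
        assert profile_distance(m, "jaccard")[0, 1] == 0.0

    def test_disjoint_profiles_jaccard_one(self):
        m = build_matrix(hits_frame([("g1", "f1", 1), ("g2", "f2", 1)]),
                         families=["f1", "f2"], genomes=["g1", "g2"])
        assert profile_distance(m, "jaccard")[0, 1] == 1.0

    def test_both_empty_defined_as_zero(self):
        m = build_matrix(hits_frame([]), families=["f1"], genomes=["g1", "g2"])
        assert profile_distance(m, "jaccard")[0, 1] == 0.0

    def test_matches_independent_set_computation(self):
        rng = np.random.default_rng(53)
        from markersieve.esp import PresenceAbsenceMatrix

        for _ in range(20):
            cells = rng.integers(0, 2, size=(5, 12)).astype(np.int8)
            m = PresenceAbsenceMatrix(
                genomes=tuple(f"g{i}" for i in range(5)),
                families=tuple(f"f{i}" for i in range(12)),
                cells=cells,
            )
            dj = profile_distance(m, "jaccard")
            dh = profile_distance(m, "hamming")
            for i in range(5):
                for j in range(5):
                    si = {k for k in range(12) if cells[i, k]}
                    sj = {k for k in range(12) if cells[j, k]}
                    union = si | sj
                    expect = 0.0 if not union else 1 - len(si & sj) / len(union)
                    assert dj[i, j] == pytest.approx(expect)
                    assert dh[i, j] == pytest.approx(
                        sum(cells[i, k] != cells[j, k] for k in range(12)) / 12
                    )

    def test_unknown_metric(self):
        m = build_matrix(hits_frame([("g1", "f1", 1), ("g2", "f1", 1)]),
                         families=["f1"], genomes=["g1", "g2"])
        with pytest.raises(ValueError):
            profile_distance(m, "euclid")


def ultrametric_heights(dend):
    tree = dend.tree().tree
    depths = []
    for leaf in tree.leaf_node_iter():
        d, nd = 0.0, leaf
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        depths.append(d)
    return depths


class TestUpgma:
    def test_two_items_merge_at_half_distance(self):
        d = np.array([[0.0, 0.4], [0.4, 0.0]])
        dend = upgma(d, labels=("a", "b"))
        assert dend.merges == [(0, 1, 0.4, 2)]
        assert ultrametric_heights(dend) == pytest.approx([0.2, 0.2])

    def test_equidistant_tie_breaks_by_index(self):
        d = np.full((3, 3), 0.6)
        np.fill_diagonal(d, 0.0)
        dend = upgma(d)
        assert dend.merges[0][:2] == (0, 1)
        assert dend.merges[1][2] == pytest.approx(0.6)

    def test_asymmetric_rejected(self):
        d = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError):
            upgma(d)

    def test_cophenetic_matches_scipy_on_random_matrices(self):
        rng = np.random.default_rng(57)
        for _ in range(25):
            d = rng.random((6, 6))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            dend = upgma(d)
            z = average(squareform(d, checks=False))
            coph = squareform(cophenet(z))
            assert np.allclose(dend.cophenetic_matrix(), coph)

    def test_ultrametric_and_permutation_isomorphic(self):
        rng = np.random.default_rng(59)
        d = rng.random((7, 7))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = tuple(f"g{i}" for i in range(7))
        dend = upgma(d, labels)
        h = ultrametric_heights(dend)
        assert max(h) - min(h) < 1e-9
        # permuting genome order gives identical cophenetic structure
        perm = rng.permutation(7)
        d2 = d[np.ix_(perm, perm)]
        dend2 = upgma(d2, tuple(labels[i] for i in perm))
        c1 = dend.cophenetic_matrix()
        c2 = dend2.cophenetic_matrix()
        inv = np.argsort(perm)
        assert np.allclose(c1, c2[np.ix_(inv, inv)])

    def test_group_structured_profiles_split_first(self):
        cfg = SimulationConfig(
            n_clades_A=2, n_clades_B=2, taxa_per_clade=3, n_outgroup=1,
            focal_size=2, n_markers=1, seed=61,
        )
        _, taxmap = simulate_species_tree(cfg)
        hits = simulate_esp_hits(taxmap, flip_rate=0.0, seed=61)
        fams = sorted(set(hits["family_id"]))
        m = build_matrix(hits, families=fams)
        dend = upgma(profile_distance(m), labels=m.genomes)
        tree = dend.tree()
        rich = taxmap.genomes_with_role("focal") | frozenset(
            g for g in taxmap.genome_ids
            if taxmap.role_of(g) == "ingroup" and taxmap.clade_of(g).startswith("B")
        )
        # the Asgard-like ESP-rich group must form one cluster
        assert rich in [s for s in dend.tree().subtree_leafsets().values()] or (
            frozenset(m.genomes) - rich
        ) in [s for s in dend.tree().subtree_leafsets().values()]
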