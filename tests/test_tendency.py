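"""Focal-clade placement labels and Venn overlap statistics."""

import dataclasses
import itertools

import numpy as np
import pytest

from markersieve import (
    TendencyLabel,
    TendencyRow,
    TendencyTable,
    classify_tendency,
    read_newick,
    simulate_gene_trees,
    simulate_species_tree,
    venn_overlap,
)
from markersieve.io import TaxonomyMap

TAXMAP = TaxonomyMap({
    "out": ("OUT", "outgroup"),
    "f1": ("FOCAL", "focal"),
    "f2": ("FOCAL", "focal"),
    "k1": ("KOR", "ingroup"),
    "k2": ("KOR", "ingroup"),
    "as1": ("ASG", "ingroup"),
    "as2": ("ASG", "ingroup"),
})
A, B = ["KOR"], ["ASG"]


def classify(newick):
    return classify_tendency(read_newick(newick, marker_id="m"), TAXMAP, A, B)


class TestClassifyTendency:
    def test_sister_pure_A(self):
        row = classify("(out,((f1,f2),(k1,k2)),(as1,as2));")
        assert row.label is TendencyLabel.WITH_A
        assert row.focal_monophyletic

    def test_sister_pure_B(self):
        row = classify("(out,((f1,f2),(as1,as2)),(k1,k2));")
        assert row.label is TendencyLabel.WITH_B

    def test_broken_focal_unresolved(self):
        row = classify("(out,((f1,k1),(f2,k2)),(as1,as2));")
        assert row.label is TendencyLabel.UNRESOLVED
        assert not row.focal_monophyletic

    def test_single_focal_leaf_unresolved(self):
        taxmap = TaxonomyMap({
            "out": ("OUT", "outgroup"), "f1": ("FOCAL", "focal"),
            "k1": ("KOR", "ingroup"), "k2": ("KOR", "ingroup"),
        })
        row = classify_tendency(
            read_newick("(out,(f1,(k1,k2)));"), taxmap, A, B
        )
        assert row.label is TendencyLabel.UNRESOLVED

    def test_even_sister_mix_unresolved(self):
        row = classify("(out,((f1,f2),(k1,as1)),(k2,as2));")
        assert row.sister_composition == {"A": 1, "B": 1, "other": 0}
        assert row.label is TendencyLabel.UNRESOLVED

    def test_no_focal_taxa_in_map_errors(self):
        taxmap = TaxonomyMap({"a": ("X", "ingroup"), "b": ("X", "ingroup")})
        with pytest.raises(ValueError):
            classify_tendency(read_newick("(a,b);"), taxmap, A, B)

    def test_invariant_to_leaf_order(self):
        r1 = classify("(out,((f1,f2),(k1,k2)),(as1,as2));")
        r2 = classify("((as2,as1),((k2,k1),(f2,f1)),out);")
        assert r1.label is r2.label is TendencyLabel.WITH_A

    def test_invariant_to_outgroup_leaf_choice(self):
        # rooting at o1 or at o2 must give the same placement label
        base = read_newick("((o1,o2),((f1,f2),(as1,as2)),(k1,k2));", marker_id="m")
        common = {
            "f1": ("FOCAL", "focal"), "f2": ("FOCAL", "focal"),
            "k1": ("KOR", "ingroup"), "k2": ("KOR", "ingroup"),
            "as1": ("ASG", "ingroup"), "as2": ("ASG", "ingroup"),
        }
        labels = set()
        for root_leaf, other in (("o1", "o2"), ("o2", "o1")):
            taxmap = TaxonomyMap(common | {
                root_leaf: ("OUT", "outgroup"), other: ("OUT", "ingroup"),
            })
            labels.add(classify_tendency(base, taxmap, A, B).label)
        assert labels == {TendencyLabel.WITH_B}

    def test_midpoint_rooting_without_outgroup(self):
        taxmap = TaxonomyMap({
            g: (c, r) for g, (c, r) in TAXMAP.assignments.items() if g != "out"
        })
        row = classify_tendency(
            read_newick("(((f1:1,f2:1):1,(as1:1,as2:1):1):1,(k1:4,k2:4):4);"),
            taxmap, A, B,
        )
        assert row.label is TendencyLabel.WITH_B

    def test_matches_truth_under_forced_grafts(self, replace_cfg):
        cfg = replace_cfg(hgt_rate=1.0, contaminant_rate=0.0,
                          graft_target="B", n_markers=50)
        species, taxmap = simulate_species_tree(cfg)
        trees, truth = simulate_gene_trees(species, taxmap, cfg)
        for t in trees:
            row = classify_tendency(t, taxmap, ["A1", "A2"], ["B1", "B2"])
            assert row.label is TendencyLabel.WITH_B
            assert truth[t.marker_id].graft_group == "B"


def table_for(labels):
    t = TendencyTable()
    for m, lab in labels.items():
        t.add(TendencyRow(m, lab, True))
    return t


class TestVennOverlap:
    def test_disjoint_sets_empty_intersection(self):
        tab = table_for({"a": TendencyLabel.WITH_A, "b": TendencyLabel.WITH_B})
        rep = venn_overlap({"s1": ["a"], "s2": ["b"]}, tab)
        assert rep.region("s1", "s2").n == 0
        assert rep.region("s1", "s2").pct_with_B is None
        assert rep.region("s1").n == rep.region("s2").n == 1

    def test_region_sizes_sum_to_union(self):
        rng = np.random.default_rng(23)
        universe = [f"m{i}" for i in range(30)]
        tab = table_for({
            m: TendencyLabel.WITH_B if rng.random() < 0.4 else TendencyLabel.WITH_A
            for m in universe
        })
        for _ in range(100):
            k = int(rng.integers(2, 5))
            sets = {
                f"s{i}": [m for m in universe if rng.random() < 0.5]
                for i in range(k)
            }
            if not any(sets.values()):
                continue
            rep = venn_overlap(sets, tab)
            union = set().union(*(set(v) for v in sets.values()))
            assert sum(r.n for r in rep.regions.values()) == len(union)
            # brute-force signature partition agrees
            for m in union:
                sig = frozenset(n for n, v in sets.items() if m in v)
                assert m in rep.regions[sig].marker_ids
            for r in rep.regions.values():
                if r.pct_with_B is not None:
                    assert 0.0 <= r.pct_with_B <= 100.0

    def test_missing_tendency_listed(self):
        tab = table_for({"a": TendencyLabel.WITH_A})
        with pytest.raises(KeyError, match="ghost"):
            venn_overlap({"s1": ["a", "ghost"], "s2": ["a"]}, tab)

    def test_set_count_bounds(self):
        tab = table_for({"a": TendencyLabel.WITH_A})
        with pytest.raises(ValueError):
            venn_overlap({"s1": ["a"]}, tab)

    def test_percentage_rounding_half_up(self):
        labels = {f"m{i}": TendencyLabel.WITH_B if i < 6 else TendencyLabel.WITH_A
                  for i in range(19)}
        tab = table_for(labels)
        ids = list(labels)
        rep = venn_overlap({"s1": ids, "s2": ids}, tab)
        assert rep.region("s1", "s2").pct_with_B == 31.6  # 6/19 = 31.578...
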