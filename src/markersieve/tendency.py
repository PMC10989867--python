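"""Classify each marker tree's placement of a focal clade, and Venn stats.

For every single-gene tree we ask: does the focal lineage affiliate with
clade series A (TACK-like) or series B (Asgard-like)?  The tree is
rooted — at the outgroup when outgroup leaves are present, else at the
midpoint — the focal clade is located, and its sister subtree's leaves
are tallied by series membership (outgroup leaves ignored).  A strict
majority of the tally decides WITH_A / WITH_B; non-monophyletic or
absent focal taxa, and mixed sisters at or below the majority threshold,
are UNRESOLVED.  Tendency labels then feed multi-set (Venn) overlap
statistics across ranked marker selections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Mapping, Optional, Sequence

import pandas as pd

from .io import TaxonomyMap
from .trees import GeneTree

__all__ = [
    "TendencyLabel",
    "TendencyRow",
    "TendencyTable",
    "VennRegion",
    "VennReport",
    "classify_tendency",
    "venn_overlap",
]


class TendencyLabel(str, Enum):
    WITH_A = "WITH_A"
    WITH_B = "WITH_B"
    UNRESOLVED = "UNRESOLVED"


@dataclass
class TendencyRow:
    marker_id: str
    label: TendencyLabel
    focal_monophyletic: bool
    sister_composition: dict[str, int] = field(default_factory=dict)


@dataclass
class TendencyTable:
    rows: dict[str, TendencyRow] = field(default_factory=dict)

    def __getitem__(self, marker_id: str) -> TendencyRow:
        return self.rows[marker_id]

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self.rows

    def __len__(self) -> int:
        return len(self.rows)

    def add(self, row: TendencyRow) -> None:
        self.rows[row.marker_id] = row

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    r.marker_id,
                    r.label.value,
                    r.focal_monophyletic,
                    r.sister_composition.get("A", 0),
                    r.sister_composition.get("B", 0),
                    r.sister_composition.get("other", 0),
                )
                for r in self.rows.values()
            ],
            columns=["marker_id", "label", "focal_monophyletic",
                     "sister_A", "sister_B", "sister_other"],
        )


def _rooted_leafsets(tree) -> dict:
    sets: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            sets[nd] = frozenset([nd.taxon.label])
        else:
            acc: frozenset = frozenset()
            for ch in nd.child_nodes():
                acc = acc | sets[ch]
            sets[nd] = acc
    return sets


def _reroot(gt: GeneTree, outgroup_leaves: Sequence[str]) -> GeneTree:
    """Root a copy of the tree: at the first outgroup pendant edge when an
    outgroup leaf is in the tree, at the midpoint otherwise."""
    rooted = gt.clone()
    tree = rooted.tree
    present = sorted(set(outgroup_leaves) & gt.leaf_set)
    if present:
        leaf = next(
            lf for lf in tree.leaf_node_iter() if lf.taxon.label == present[0]
        )
        tree.reroot_at_edge(leaf.edge, update_bipartitions=False)
    else:
        if all(nd.edge.length is not None for nd in tree.preorder_node_iter()
               if nd.parent_node is not None):
            tree.reroot_at_midpoint(update_bipartitions=False)
        else:
            leaf = next(iter(tree.leaf_node_iter()))
            tree.reroot_at_edge(leaf.edge, update_bipartitions=False)
    return rooted


def classify_tendency(
    tree: GeneTree,
    taxmap: TaxonomyMap,
    groupsA: Sequence[str],
    groupsB: Sequence[str],
    majority: float = 0.5,
) -> TendencyRow:
    """Label one marker tree's placement of the focal clade.

    ``groupsA``/``groupsB`` are clade names from the taxonomy map.  The
    label is WITH_A (WITH_B) when the focal clade is monophyletic and
    more than ``majority`` of its sister's non-outgroup leaves belong to
    series A (B); everything else is UNRESOLVED.
    """
    focal_all = taxmap.genomes_with_role("focal")
    if not focal_all:
        raise ValueError("taxonomy map defines no focal genomes")
    for leaf in tree.leaf_ids:
        if leaf not in taxmap:
            raise ValueError(f"leaf {leaf!r} missing from taxonomy map")
    groupsA = set(groupsA)
    groupsB = set(groupsB)

    focal_present = focal_all & tree.leaf_set
    if len(focal_present) < 2:
        return TendencyRow(tree.marker_id, TendencyLabel.UNRESOLVED, False)

    rooted = _reroot(tree, sorted(taxmap.genomes_with_role("outgroup")))
    sets = _rooted_leafsets(rooted.tree)
    focal_node = None
    for nd, below in sets.items():
        if below == focal_present and nd.parent_node is not None:
            focal_node = nd
            break
    if focal_node is None:
        return TendencyRow(tree.marker_id, TendencyLabel.UNRESOLVED, False)

    sister_leaves = sets[focal_node.parent_node] - focal_present
    comp = {"A": 0, "B": 0, "other": 0}
    for leaf in sister_leaves:
        clade, role = taxmap.assignments[leaf]
        if role == "outgroup":
            continue
        if clade in groupsA:
            comp["A"] += 1
        elif clade in groupsB:
            comp["B"] += 1
        else:
            comp["other"] += 1
    total = sum(comp.values())
    label = TendencyLabel.UNRESOLVED
    if total > 0:
        if comp["A"] / total > majority:
            label = TendencyLabel.WITH_A
        elif comp["B"] / total > majority:
            label = TendencyLabel.WITH_B
    return TendencyRow(tree.marker_id, label, True, comp)


def classify_all(
    trees: Sequence[GeneTree],
    taxmap: TaxonomyMap,
    groupsA: Sequence[str],
    groupsB: Sequence[str],
    majority: float = 0.5,
) -> TendencyTable:
    table = TendencyTable()
    for t in trees:
        table.add(classify_tendency(t, taxmap, groupsA, groupsB, majority))
    return table


# ---------------------------------------------------------------------------
# Venn overlap


@dataclass
class VennRegion:
    signature: frozenset[str]  # the exact set-membership of this region
    marker_ids: frozenset[str]
    n: int
    n_with_B: int
    pct_with_B: Optional[float]  # one decimal, half-up; None for empty region


@dataclass
class VennReport:
    regions: dict[frozenset[str], VennRegion]
    set_names: tuple[str, ...]

    def region(self, *names: str) -> VennRegion:
        return self.regions[frozenset(names)]

    @property
    def core(self) -> VennRegion:
        return self.regions[frozenset(self.set_names)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sig, reg in sorted(self.regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))):
            rows.append(
                ("&".join(sorted(sig)), reg.n, reg.n_with_B,
                 "" if reg.pct_with_B is None else reg.pct_with_B)
            )
        return pd.DataFrame(rows, columns=["region", "n", "n_with_B", "pct_with_B"])


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def venn_overlap(
    sets: Mapping[str, Sequence[str]],
    tendencies: TendencyTable,
) -> VennReport:
    """Partition the union of 2-4 marker sets into exclusive Venn regions.

    Each marker falls in exactly one region (its membership signature);
    per region we report the count and the percentage labelled WITH_B,
    rounded to one decimal, half-up.
    """
    if not (2 <= len(sets) <= 4):
        raise ValueError("venn_overlap takes between 2 and 4 named sets")
    as_sets = {name: set(v) for name, v in sets.items()}
    union = set().union(*as_sets.values())
    missing = sorted(m for m in union if m not in tendencies)
    if missing:
        raise KeyError(f"markers without tendency labels: {missing}")

    by_sig: dict[frozenset[str], set[str]] = {}
    for m in union:
        sig = frozenset(name for name, s in as_sets.items() if m in s)
        by_sig.setdefault(sig, set()).add(m)

    # every nonempty signature over the power set (minus the empty one)
    names = tuple(sets)
    regions: dict[frozenset[str], VennRegion] = {}
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            sig = frozenset(combo)
            members = frozenset(by_sig.get(sig, set()))
            n = len(members)
            n_b = sum(1 for m in members if tendencies[m].label is TendencyLabel.WITH_B)
            pct = _round1(100.0 * n_b / n) if n else None
            regions[sig] = VennRegion(sig, members, n, n_b, pct)
    return VennReport(regions=regions, set_names=names)
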