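"""Gene-tree container and newick input/output.

A :class:`GeneTree` is an (usually unrooted) binary tree over genome-id
leaves.  Internal node labels may carry dual branch supports written as
``"97/98"``, read as UFBoot/SH-aLRT percentages; a bare number is stored
as UFBoot only.  Parsing and printing are delegated to :mod:`dendropy`;
this module adds validation, support-label handling and split
(bipartition) utilities used throughout the pipeline.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy

__all__ = [
    "GeneTree",
    "NewickParseError",
    "TreeValidationError",
    "parse_support_label",
    "format_support_label",
    "read_newick",
    "write_newick",
]


class NewickParseError(ValueError):
    """Malformed newick text; carries the character offset when known."""

    def __init__(self, message: str, offset: Optional[int] = None):
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)
        self.offset = offset


class TreeValidationError(ValueError):
    """Structurally valid newick violating a tree invariant."""


def _check_parentheses(text: str) -> None:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError("unbalanced ')'", offset=i)
    if depth != 0:
        raise NewickParseError("unclosed '('", offset=len(text))


def parse_support_label(label: Optional[str]) -> tuple[Optional[float], Optional[float]]:
    """Split an internal node label into (ufboot, shalrt).

    ``"97/98"`` -> (97.0, 98.0); ``"85"`` -> (85.0, None); empty or
    non-numeric labels -> (None, None).  Missing components stay missing —
    never coerced to 0, since 0 is a meaningful support value.
    """
    if label is None or label == "":
        return (None, None)
    parts = label.split("/")
    try:
        if len(parts) == 1:
            return (float(parts[0]), None)
        if len(parts) == 2:
            return (float(parts[0]), float(parts[1]))
    except ValueError:
        return (None, None)
    return (None, None)


def format_support_label(ufboot: Optional[float], shalrt: Optional[float]) -> Optional[str]:
    def fmt(x: float) -> str:
        return f"{x:g}"

    if ufboot is None and shalrt is None:
        return None
    if shalrt is None:
        return fmt(ufboot)
    if ufboot is None:
        return "/" + fmt(shalrt)
    return f"{fmt(ufboot)}/{fmt(shalrt)}"


@dataclass
class GeneTree:
    """A tree over genome-id leaves, optionally carrying dual supports.

    The underlying :class:`dendropy.Tree` keeps raw internal-node labels;
    supports are parsed on demand.  Unrooted trees are represented with a
    trifurcating seed node; rooting is always an explicit operation.
    """

    marker_id: str
    tree: dendropy.Tree = field(repr=False)

    # -- construction ----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, marker_id: str = "") -> "GeneTree":
        _check_parentheses(text)
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            if "uplicate tax" in str(exc):
                raise TreeValidationError(f"duplicate leaf ids: {exc}") from exc
            raise NewickParseError(f"newick parse failed: {exc}") from exc
        gt = cls(marker_id=marker_id, tree=tree)
        gt.validate()
        return gt

    def validate(self) -> None:
        seen: set[str] = set()
        for nd in self.tree:
            if nd.taxon is not None:
                name = nd.taxon.label
                if name in seen:
                    raise TreeValidationError(f"duplicate leaf id {name!r}")
                seen.add(name)
            if nd.edge.length is not None and nd.edge.length < 0:
                raise TreeValidationError(
                    f"negative branch length {nd.edge.length} above "
                    f"{nd.taxon.label if nd.taxon else 'internal node'}"
                )
            if nd.is_internal():
                uf, sh = parse_support_label(nd.label)
                for val, kind in ((uf, "UFBoot"), (sh, "SH-aLRT")):
                    if val is not None and not (0.0 <= val <= 100.0):
                        raise TreeValidationError(
                            f"{kind} support {val} outside [0, 100]"
                        )

    def clone(self) -> "GeneTree":
        return GeneTree(self.marker_id, self.tree.clone(depth=1))

    # -- leaves and splits -----------------------------------------------

    @property
    def leaf_ids(self) -> tuple[str, ...]:
        return tuple(lf.taxon.label for lf in self.tree.leaf_node_iter())

    @property
    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaf_ids)

    def subtree_leafsets(self) -> dict:
        """Map node -> frozenset of leaf labels below it (seed node included)."""
        sets: dict = {}
        for nd in self.tree.postorder_node_iter():
            if nd.is_leaf():
                sets[nd] = frozenset([nd.taxon.label])
            else:
                acc: frozenset = frozenset()
                for ch in nd.child_nodes():
                    acc = acc | sets[ch]
                sets[nd] = acc
        return sets

    def splits(self, nontrivial_only: bool = True) -> frozenset[frozenset[str]]:
        """Canonical bipartitions: each edge's side NOT containing the
        lexicographically smallest leaf.  Unrooted semantics — the seed
        node's edge induces no split."""
        leaves = self.leaf_set
        if not leaves:
            return frozenset()
        anchor = min(leaves)
        sets = self.subtree_leafsets()
        out = set()
        for nd, below in sets.items():
            if nd is self.tree.seed_node:
                continue
            side = leaves - below if anchor in below else below
            if nontrivial_only and (len(side) < 2 or len(leaves - side) < 2):
                continue
            out.add(side)
        return frozenset(out)

    def same_topology(self, other: "GeneTree") -> bool:
        return self.leaf_set == other.leaf_set and self.splits() == other.splits()

    def edge_supports(self) -> dict[frozenset, tuple[Optional[float], Optional[float]]]:
        """Map canonical nontrivial split -> (ufboot, shalrt), labelled edges only."""
        leaves = self.leaf_set
        anchor = min(leaves)
        sets = self.subtree_leafsets()
        out = {}
        for nd, below in sets.items():
            if nd is self.tree.seed_node or nd.is_leaf():
                continue
            side = leaves - below if anchor in below else below
            if len(side) < 2 or len(leaves - side) < 2:
                continue
            pair = parse_support_label(nd.label)
            if pair != (None, None):
                out[side] = pair
        return out

    # -- iteration helpers ----------------------------------------------

    def leaf_nodes(self) -> Iterator:
        return self.tree.leaf_node_iter()

    # -- output ----------------------------------------------------------

    def to_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
        )
        return s.strip() + "\n"


def read_newick(text: str, marker_id: str = "") -> GeneTree:
    """Parse a single newick string into a :class:`GeneTree`."""
    return GeneTree.from_newick(text, marker_id=marker_id)


def write_newick(tree: GeneTree) -> str:
    return tree.to_newick()


def read_newick_file(path, marker_id: str = "") -> GeneTree:
    with open(path) as fh:
        return read_newick(fh.read(), marker_id=marker_id)


def write_newick_file(tree: GeneTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick())
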