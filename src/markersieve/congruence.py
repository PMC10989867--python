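"""Rank marker genes by lineage-monophyly congruence of their gene trees.

Each marker's single-gene tree is scored by the fraction of predefined,
well-established lineages it recovers as monophyletic.  On an unrooted
tree a lineage is monophyletic iff some edge's bipartition isolates
exactly the lineage members present as leaves.  Markers are ranked by
score and the top fraction (e.g. 25% / 50%) selected; discordant trees —
contaminated sequences, transfers — recover fewer lineages and sink.

Lineages with fewer than ``min_present`` members in a tree are excluded
from the denominator rather than counted as successes: a singleton is
vacuously monophyletic and would inflate the score of sparse markers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

from .trees import GeneTree

__all__ = [
    "CladeDefinition",
    "Monophyly",
    "CongruenceScore",
    "RankedSelection",
    "is_monophyletic",
    "score_marker",
    "rank_and_select",
    "clades_from_taxonomy",
]


class Monophyly(str, Enum):
    MONOPHYLETIC = "monophyletic"
    VIOLATED = "violated"
    NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class CladeDefinition:
    """A named lineage given as a genome-id set, the unit of monophyly tests."""

    name: str
    members: frozenset[str]
    min_present: int = 2

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"clade {self.name!r} has no members")
        if self.min_present < 2:
            raise ValueError("min_present must be >= 2")


def clades_from_taxonomy(taxmap, roles: Sequence[str] = ("ingroup", "focal")) -> list[CladeDefinition]:
    """One CladeDefinition per clade name in a TaxonomyMap (selected roles)."""
    out = []
    for clade in taxmap.clades():
        members = frozenset(
            g for g in taxmap.members(clade) if taxmap.role_of(g) in roles
        )
        if members:
            out.append(CladeDefinition(clade, members))
    return out


def is_monophyletic(tree: GeneTree, clade: CladeDefinition) -> Monophyly:
    """Test whether a lineage forms a clade on an unrooted gene tree.

    The lineage is first restricted to members actually present as
    leaves.  With fewer than ``min_present`` present the test is not
    evaluable.  Present members equal to the full leaf set are vacuously
    monophyletic.
    """
    leaves = tree.leaf_set
    present = frozenset(clade.members) & leaves
    if len(present) < clade.min_present:
        return Monophyly.NOT_EVALUABLE
    if present == leaves:
        return Monophyly.MONOPHYLETIC
    rest = leaves - present
    for below in tree.subtree_leafsets().values():
        if below == present or below == rest:
            return Monophyly.MONOPHYLETIC
    return Monophyly.VIOLATED


@dataclass
class CongruenceScore:
    """Per-marker monophyly scorecard: score = n_monophyletic / n_evaluable."""

    marker_id: str
    n_evaluable: int
    n_monophyletic: int
    per_clade: dict[str, Monophyly] = field(default_factory=dict)

    @property
    def score(self) -> Optional[float]:
        if self.n_evaluable == 0:
            return None
        return self.n_monophyletic / self.n_evaluable


def score_marker(tree: GeneTree, clades: Sequence[CladeDefinition]) -> CongruenceScore:
    if not clades:
        raise ValueError("need at least one clade definition")
    verdicts = {c.name: is_monophyletic(tree, c) for c in clades}
    evaluable = [v for v in verdicts.values() if v is not Monophyly.NOT_EVALUABLE]
    mono = sum(1 for v in evaluable if v is Monophyly.MONOPHYLETIC)
    return CongruenceScore(
        marker_id=tree.marker_id,
        n_evaluable=len(evaluable),
        n_monophyletic=mono,
        per_clade=verdicts,
    )


@dataclass
class RankedSelection:
    """Descending-score ordering of markers with a top-fraction prefix."""

    ranked: list[str]
    top_fraction: float
    selected: list[str]

    def __post_init__(self):
        assert self.selected == self.ranked[: len(self.selected)]


def rank_and_select(
    scores: Sequence[CongruenceScore],
    top_fraction: float,
    k_override: Optional[int] = None,
) -> RankedSelection:
    """Order markers by (score desc, n_evaluable desc, id asc) and take a prefix.

    Markers whose score is undefined (no evaluable lineage) are excluded
    from the ranking.  k defaults to half-up round(top_fraction * n); the
    explicit override reproduces published set sizes when the paper-style
    percentage does not land on the exact quarter.
    """
    if not scores:
        raise ValueError("no scores to rank")
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must lie in (0, 1]")
    rankable = [s for s in scores if s.n_evaluable > 0]
    rankable.sort(key=lambda s: (-s.score, -s.n_evaluable, s.marker_id))
    ranked = [s.marker_id for s in rankable]
    n = len(ranked)
    if k_override is not None:
        if k_override > n:
            raise ValueError(f"k_override {k_override} exceeds {n} ranked markers")
        k = k_override
    else:
        k = int(math.floor(top_fraction * n + 0.5))
    return RankedSelection(ranked=ranked, top_fraction=top_fraction, selected=ranked[:k])


def scores_to_frame(scores: Sequence[CongruenceScore]) -> pd.DataFrame:
    """Tabulate scores, one row per marker with per-clade verdict columns."""
    clade_names: dict[str, None] = {}
    for s in scores:
        for name in s.per_clade:
            clade_names.setdefault(name)
    rows = []
    for s in scores:
        row = {
            "marker_id": s.marker_id,
            "n_evaluable": s.n_evaluable,
            "n_monophyletic": s.n_monophyletic,
            "score": s.score,
        }
        for name in clade_names:
            v = s.per_clade.get(name)
            row[f"clade:{name}"] = v.value if v is not None else ""
        rows.append(row)
    return pd.DataFrame(rows)
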