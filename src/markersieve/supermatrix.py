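"""Concatenate per-marker alignments into an occupancy-filtered supermatrix.

A column is kept when it is "present" — not a gap ``-`` and not missing
``?`` ('X' is an unknown residue, hence present) — in at least
``ceil(threshold * n_taxa)`` rows, the at-least-60%-of-taxa rule used
for phylogenomic matrices.  Genomes lacking a marker contribute all-gap
rows and count as absent.  Also provides clade down-sampling: choosing
quota-sized representative subsets of over-represented clades by greedy
phylogenetic-diversity maximization on a guide tree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .io import Alignment, TaxonomyMap
from .trees import GeneTree

__all__ = ["SuperMatrix", "DownsamplePlan", "concatenate", "downsample"]

_ABSENT = ("-", "?")


@dataclass
class SuperMatrix:
    taxa: tuple[str, ...]
    rows: dict[str, str]
    partitions: dict[str, tuple[int, int]]  # marker -> [start, end) post-filter
    occupancy_threshold: float
    n_columns_kept: int
    n_columns_dropped: int

    @property
    def length(self) -> int:
        return self.n_columns_kept

    def to_alignment(self, marker_id: str = "supermatrix") -> Alignment:
        return Alignment(marker_id=marker_id, rows=dict(self.rows))

    def marker_summary(self):
        import pandas as pd

        rows = []
        for m, (s, e) in self.partitions.items():
            rows.append((m, s + 1 if e > s else 0, e, e - s))
        return pd.DataFrame(rows, columns=["marker_id", "start", "end", "n_columns"])


def concatenate(
    alignments: Sequence[Alignment],
    taxa: Sequence[str],
    threshold: float,
) -> SuperMatrix:
    """Concatenate alignments over a fixed taxon order with column filtering.

    Presence of a column in a taxon means the residue is neither ``-``
    nor ``?``; the column survives when present in at least
    ``ceil(threshold * len(taxa))`` taxa.  Partitions record each
    marker's post-filter interval (possibly empty).
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    if not taxa:
        raise ValueError("taxon list is empty")
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate genome ids in taxon list")
    seen = set()
    for aln in alignments:
        if aln.marker_id in seen:
            raise ValueError(f"duplicate marker {aln.marker_id!r}")
        seen.add(aln.marker_id)

    taxa = tuple(taxa)
    need = math.ceil(threshold * len(taxa))
    out_rows = {g: [] for g in taxa}
    partitions: dict[str, tuple[int, int]] = {}
    kept_total = 0
    dropped_total = 0
    for aln in alignments:
        L = aln.length
        block = np.full((len(taxa), L), "-", dtype="U1")
        for gi, g in enumerate(taxa):
            seq = aln.rows.get(g)
            if seq is not None:
                block[gi] = list(seq)
        present = ~np.isin(block, _ABSENT)
        keep = present.sum(axis=0) >= need
        kept = int(keep.sum())
        start = kept_total
        kept_total += kept
        dropped_total += L - kept
        partitions[aln.marker_id] = (start, kept_total)
        sub = block[:, keep]
        for gi, g in enumerate(taxa):
            out_rows[g].append("".join(sub[gi]))
    rows = {g: "".join(parts) for g, parts in out_rows.items()}
    return SuperMatrix(
        taxa=taxa,
        rows=rows,
        partitions=partitions,
        occupancy_threshold=threshold,
        n_columns_kept=kept_total,
        n_columns_dropped=dropped_total,
    )


# ---------------------------------------------------------------------------
# clade down-sampling


@dataclass
class DownsamplePlan:
    quotas: dict[str, int]
    selected: frozenset[str]
    method: str
    per_clade: dict[str, tuple[str, ...]] = field(default_factory=dict)


def _patristic(tree: GeneTree) -> tuple[dict[str, int], np.ndarray]:
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.tree.taxon_namespace, key=lambda t: t.label)
    index = {t.label: i for i, t in enumerate(taxa)}
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return index, d


def _greedy_diverse(members: list[str], k: int, index, d) -> list[str]:
    """Quota-sized subset greedily maximizing summed pairwise path distance.

    Seeded with the farthest pair; then repeatedly adds the member whose
    summed distance to the current pick is largest.  All ties break on
    the lexicographically smallest id, so output is deterministic.
    """
    members = sorted(members)
    if k >= len(members):
        return members
    if k == 1:
        totals = [(-sum(d[index[m], index[o]] for o in members), m) for m in members]
        return [min(totals)[1]]
    best = None
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            key = (-d[index[a], index[b]], a, b)
            if best is None or key < best:
                best = key
    chosen = [best[1], best[2]]
    while len(chosen) < k:
        cand = None
        for m in members:
            if m in chosen:
                continue
            gain = sum(d[index[m], index[c]] for c in chosen)
            key = (-gain, m)
            if cand is None or key < cand:
                cand = key
        chosen.append(cand[1])
    return sorted(chosen)


def downsample(
    tree: GeneTree,
    taxmap: TaxonomyMap,
    quotas: Mapping[str, int],
    method: str = "diversity_greedy",
    seed: int = 0,
) -> DownsamplePlan:
    """Pick per-clade representative genomes, capping over-represented clades.

    Focal and outgroup genomes always pass; clades without a quota are
    kept whole.  ``diversity_greedy`` maximizes summed pairwise patristic
    distance on the guide tree; ``first_k`` takes the k smallest ids.
    """
    if method not in ("diversity_greedy", "first_k"):
        raise ValueError(f"unknown method {method!r}")
    clades = set(taxmap.clades())
    for clade, q in quotas.items():
        if q < 1:
            raise ValueError(f"quota for {clade!r} must be >= 1")
        if clade not in clades:
            warnings.warn(f"quota for clade {clade!r} not present in taxonomy")

    index = d = None
    if method == "diversity_greedy":
        index, d = _patristic(tree)

    selected: set[str] = set()
    per_clade: dict[str, tuple[str, ...]] = {}
    for clade in taxmap.clades():
        members = sorted(taxmap.members(clade) & set(tree.leaf_ids))
        if not members:
            continue
        roles = {taxmap.role_of(g) for g in members}
        if roles & {"focal", "outgroup"} or clade not in quotas:
            pick = members
        else:
            k = min(quotas[clade], len(members))
            if method == "first_k":
                pick = members[:k]
            else:
                pick = _greedy_diverse(members, k, index, d)
        per_clade[clade] = tuple(pick)
        selected |= set(pick)
    return DownsamplePlan(
        quotas=dict(quotas), selected=frozenset(selected), method=method,
        per_clade=per_clade,
    )
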