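"""Eukaryotic-signature-protein profiles: presence/absence and UPGMA.

Genomes are profiled by which ESP (or CdvB/Snf7-type) families they
encode, hit tables become a binary matrix, pairwise profile distances
(Jaccard by default — robust to profile-size differences) feed a
hand-rolled UPGMA with an explicit tie rule, yielding an ultrametric
dendrogram whose cophenetic distances reproduce the linkage values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trees import GeneTree

__all__ = [
    "PresenceAbsenceMatrix",
    "Dendrogram",
    "build_matrix",
    "profile_distance",
    "upgma",
]


@dataclass
class PresenceAbsenceMatrix:
    genomes: tuple[str, ...]
    families: tuple[str, ...]
    cells: np.ndarray  # shape (n_genomes, n_families), dtype int8, 0/1

    def __post_init__(self):
        if self.cells.shape != (len(self.genomes), len(self.families)):
            raise ValueError("cell matrix shape does not match labels")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("matrix must be binary")

    def row(self, genome_id: str) -> np.ndarray:
        return self.cells[self.genomes.index(genome_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=list(self.genomes),
                            columns=list(self.families))


def build_matrix(
    hits: pd.DataFrame,
    families: Sequence[str],
    genomes: Optional[Sequence[str]] = None,
) -> PresenceAbsenceMatrix:
    """Binarize a hit table: cell = 1 iff the genome has >=1 hit to the family.

    Duplicate (genome, family) rows merge; genomes/families with no rows
    appear all-zero.  Genome order defaults to sorted ids seen in the
    table.
    """
    key = "family_id" if "family_id" in hits.columns else "marker_id"
    if genomes is None:
        genomes = sorted(set(hits["genome_id"]))
    genomes = tuple(genomes)
    families = tuple(families)
    gi = {g: i for i, g in enumerate(genomes)}
    fi = {f: i for i, f in enumerate(families)}
    cells = np.zeros((len(genomes), len(families)), dtype=np.int8)
    for r in hits.itertuples(index=False):
        g = getattr(r, "genome_id")
        f = getattr(r, key)
        n = int(getattr(r, "n_copies", 1))
        if n > 0 and g in gi and f in fi:
            cells[gi[g], fi[f]] = 1
    return PresenceAbsenceMatrix(genomes=genomes, families=families, cells=cells)


def profile_distance(m: PresenceAbsenceMatrix, metric: str = "jaccard") -> np.ndarray:
    """Pairwise distances between genome profiles (symmetric, zero diagonal).

    jaccard(g,h) = 1 - |g&h| / |g|h|union|, defined as 0 when both
    profiles are empty; hamming = fraction of differing families.
    """
    if len(m.genomes) < 2:
        raise ValueError("need at least two genomes")
    x = m.cells.astype(bool)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "jaccard":
                union = int((x[i] | x[j]).sum())
                inter = int((x[i] & x[j]).sum())
                dij = 0.0 if union == 0 else 1.0 - inter / union
            elif metric == "hamming":
                dij = float((x[i] != x[j]).mean())
            else:
                raise ValueError(f"unknown metric {metric!r}")
            d[i, j] = d[j, i] = dij
    return d


@dataclass
class Dendrogram:
    """UPGMA result: merge list (scipy-linkage-like) and an ultrametric tree."""

    labels: tuple[str, ...]
    merges: list[tuple[int, int, float, int]]  # (idx_i, idx_j, distance, size)
    newick: str
    _coph: np.ndarray = field(repr=False, default=None)

    def tree(self) -> GeneTree:
        return GeneTree.from_newick(self.newick, marker_id="upgma")

    def cophenetic_matrix(self) -> np.ndarray:
        """Pairwise merge distances, in ``labels`` order (equals 2x merge height)."""
        return self._coph

    def linkage_matrix(self) -> np.ndarray:
        return np.array(
            [[i, j, dist, size] for i, j, dist, size in self.merges], dtype=float
        )


def upgma(d: np.ndarray, labels: Optional[Sequence[str]] = None) -> Dendrogram:
    """Average-linkage (size-weighted) agglomeration of a distance matrix.

    Repeatedly merges the closest pair at height distance/2, updating
    distances as the size-weighted mean; ties break on the smallest
    (row, col) cluster-index pair, so output is deterministic.  The
    resulting tree is ultrametric and its cophenetic distances equal the
    merge distances.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    if labels is None:
        labels = tuple(f"g{i + 1}" for i in range(n))
    labels = tuple(labels)
    if len(labels) != n:
        raise ValueError("label count does not match matrix size")
    if n < 2:
        raise ValueError("need at least two items")

    # active cluster state, keyed by creation index (leaves are 0..n-1)
    size = {i: 1 for i in range(n)}
    height = {i: 0.0 for i in range(n)}
    nwk = {i: labels[i] for i in range(n)}
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    merges: list[tuple[int, int, float, int]] = []
    coph = np.zeros((n, n))
    nxt = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (dist[(i, j)], i, j)
                if best is None or key < best:
                    best = key
        dij, i, j = best
        h = dij / 2.0
        new = nxt
        nxt += 1
        size[new] = size[i] + size[j]
        height[new] = h
        nwk[new] = (
            f"({nwk[i]}:{h - height[i]:.10g},{nwk[j]}:{h - height[j]:.10g})"
        )
        members[new] = members[i] + members[j]
        for a in members[i]:
            for b in members[j]:
                coph[a, b] = coph[b, a] = dij
        merges.append((i, j, dij, size[new]))
        active = [k for k in active if k not in (i, j)]
        for k in active:
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            dist[(min(k, new), max(k, new))] = (
                size[i] * dik + size[j] * djk
            ) / size[new]
        active.append(new)
    root = active[0]
    return Dendrogram(
        labels=labels, merges=merges, newick=nwk[root] + ";", _coph=coph
    )
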