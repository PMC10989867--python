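"""Pool published marker sets into a nonredundant catalog with provenance.

Phylogenomic studies publish overlapping marker lists under mixed
accession namespaces (arCOG, COG, TIGRFAM, asCOG...).  Redundancy here is
string-normalized accession equality (case-fold, version-suffix strip)
plus an explicit, auditable alias table for cross-namespace synonyms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "MarkerCatalog",
    "CatalogEntry",
    "normalize_accession",
    "dereplicate",
    "subset_catalog",
    "count_by_source",
    "read_hit_table",
    "single_copy_genomes",
]

_VERSION_SUFFIX = re.compile(r"\.\d+$")
MAX_ALIAS_DEPTH = 10


def normalize_accession(acc: str) -> str:
    """Case-fold and strip a trailing version suffix (``.1``, ``.2`` ...)."""
    return _VERSION_SUFFIX.sub("", acc.strip()).casefold()


@dataclass(frozen=True)
class CatalogEntry:
    marker_id: str  # canonical (normalized, alias-resolved) accession
    sources: frozenset[str]
    aliases: frozenset[str]  # raw accessions observed for this marker


@dataclass
class MarkerCatalog:
    entries: list[CatalogEntry] = field(default_factory=list)
    source_sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        ids = [e.marker_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate marker ids in catalog")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def marker_ids(self) -> list[str]:
        return [e.marker_id for e in self.entries]

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in set(self.marker_ids)

    def entry(self, marker_id: str) -> CatalogEntry:
        for e in self.entries:
            if e.marker_id == marker_id:
                return e
        raise KeyError(marker_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.marker_id, ";".join(sorted(e.sources)), ";".join(sorted(e.aliases)))
                for e in self.entries
            ],
            columns=["marker_id", "sources", "aliases"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "MarkerCatalog":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        entries = [
            CatalogEntry(
                marker_id=r.marker_id,
                sources=frozenset(s for s in r.sources.split(";") if s),
                aliases=frozenset(a for a in r.aliases.split(";") if a),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(entries=entries)


def _resolve_alias(acc: str, alias_map: Mapping[str, str]) -> str:
    seen = [acc]
    cur = acc
    for _ in range(MAX_ALIAS_DEPTH):
        nxt = alias_map.get(cur)
        if nxt is None:
            return cur
        nxt = normalize_accession(nxt)
        if nxt in seen:
            raise ValueError(f"alias cycle involving {acc!r}: {seen + [nxt]}")
        seen.append(nxt)
        cur = nxt
    raise ValueError(
        f"alias chain from {acc!r} longer than {MAX_ALIAS_DEPTH} (cycle suspicion)"
    )


def dereplicate(
    source_sets: Mapping[str, Sequence[str]],
    alias_map: Optional[Mapping[str, str]] = None,
) -> MarkerCatalog:
    """Merge named accession lists into a nonredundant catalog.

    Accessions are normalized, then chased through the (normalized) alias
    map to a canonical id.  Each entry records every source set that
    contributed it and every raw spelling observed.  Catalog order is
    first-appearance order over the input sets.
    """
    if not source_sets or all(len(v) == 0 for v in source_sets.values()):
        raise ValueError("no source sets to pool")
    norm_aliases = (
        {normalize_accession(k): v for k, v in alias_map.items()} if alias_map else {}
    )
    order: list[str] = []
    sources: dict[str, set[str]] = {}
    raw: dict[str, set[str]] = {}
    for set_name, accs in source_sets.items():
        for acc in accs:
            canon = _resolve_alias(normalize_accession(acc), norm_aliases)
            if canon not in sources:
                order.append(canon)
                sources[canon] = set()
                raw[canon] = set()
            sources[canon].add(set_name)
            raw[canon].add(acc)
    entries = [
        CatalogEntry(m, frozenset(sources[m]), frozenset(raw[m])) for m in order
    ]
    return MarkerCatalog(entries=entries, source_sets={k: list(v) for k, v in source_sets.items()})


def subset_catalog(cat: MarkerCatalog, ids: Sequence[str]) -> MarkerCatalog:
    """Order-preserving subset by canonical id; unknown ids are an error."""
    wanted = [normalize_accession(i) for i in ids]
    known = set(cat.marker_ids)
    unknown = [i for i in wanted if i not in known]
    if unknown:
        raise KeyError(f"ids not in catalog: {sorted(set(unknown))}")
    keep = set(wanted)
    entries = [e for e in cat.entries if e.marker_id in keep]
    return MarkerCatalog(entries=entries, source_sets=cat.source_sets)


def count_by_source(cat: MarkerCatalog, source: str) -> int:
    """Number of catalog entries contributed by the named source set."""
    known = set()
    for e in cat.entries:
        known |= e.sources
    if cat.source_sets:
        known |= set(cat.source_sets)
    if source not in known:
        raise KeyError(f"unknown source set {source!r}")
    return sum(1 for e in cat.entries if source in e.sources)


# ---------------------------------------------------------------------------
# hit tables


def read_hit_table(path) -> pd.DataFrame:
    """Read a (genome_id, marker_id|family_id, n_copies) TSV, merging duplicates."""
    df = pd.read_csv(path, sep="\t", dtype={"n_copies": int})
    key = "marker_id" if "marker_id" in df.columns else "family_id"
    df = df.groupby(["genome_id", key], as_index=False)["n_copies"].sum()
    return df


def single_copy_genomes(hits: pd.DataFrame, marker_id: str) -> frozenset[str]:
    """Genomes carrying the marker in exactly one copy (single-copy orthodoxy)."""
    key = "marker_id" if "marker_id" in hits.columns else "family_id"
    sel = hits[(hits[key] == marker_id) & (hits["n_copies"] == 1)]
    return frozenset(sel["genome_id"])
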