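"""Flat-file formats: aligned FASTA, taxonomy/catalog/hit TSVs, partition files.

Internal coordinates are 0-based half-open; partition files are written
1-based inclusive, the convention of common phylogenetics partition
formats (RAxML/IQ-TREE style ``name = start-end``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "TaxonomyMap",
    "AlignmentError",
    "read_fasta",
    "write_fasta",
    "read_taxonomy",
    "write_taxonomy",
    "write_partitions",
]

# 20 standard residues + ambiguity codes; '-' gap and '?' missing.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBZJUOX-?*")

ROLES = ("ingroup", "outgroup", "focal")


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """An aligned set of amino-acid sequences for one marker.

    rows map genome-id -> residue string; all rows share one length.
    Columns are addressed 0-based half-open.
    """

    marker_id: str
    rows: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise AlignmentError(
                f"ragged alignment for {self.marker_id!r}: row lengths {sorted(lengths)}"
            )
        for gid, seq in self.rows.items():
            bad = set(seq.upper()) - AA_ALPHABET
            if bad:
                raise AlignmentError(
                    f"illegal characters {sorted(bad)} in row {gid!r} of {self.marker_id!r}"
                )

    @property
    def length(self) -> int:
        for s in self.rows.values():
            return len(s)
        return 0

    @property
    def genome_ids(self) -> tuple[str, ...]:
        return tuple(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def read_fasta(path, marker_id: Optional[str] = None) -> Alignment:
    """Read an aligned FASTA file; rejects ragged alignments.

    Sequences are upper-cased ('.' treated as '-'); the marker id
    defaults to the file stem.
    """
    path = Path(path)
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise AlignmentError(f"duplicate sequence id {rec.id!r} in {path}")
        rows[rec.id] = str(rec.seq).upper().replace(".", "-")
    return Alignment(marker_id=marker_id or path.stem, rows=rows)


def write_fasta(aln: Alignment, path, width: int = 60) -> None:
    """Write an alignment wrapped at a fixed line width (round-trip stable)."""
    with open(path, "w") as fh:
        for gid, seq in aln.rows.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def alignment_to_records(aln: Alignment) -> list[SeqRecord]:
    return [SeqRecord(Seq(s), id=g, description="") for g, s in aln.rows.items()]


@dataclass
class TaxonomyMap:
    """genome-id -> (clade name, role); role is ingroup, outgroup or focal."""

    assignments: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        for gid, (clade, role) in self.assignments.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for genome {gid!r}")

    def clade_of(self, genome_id: str) -> str:
        return self.assignments[genome_id][0]

    def role_of(self, genome_id: str) -> str:
        return self.assignments[genome_id][1]

    def clades(self) -> list[str]:
        seen: dict[str, None] = {}
        for clade, _ in self.assignments.values():
            seen.setdefault(clade)
        return list(seen)

    def members(self, clade: str) -> frozenset[str]:
        return frozenset(g for g, (c, _) in self.assignments.items() if c == clade)

    def genomes_with_role(self, role: str) -> frozenset[str]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return frozenset(g for g, (_, r) in self.assignments.items() if r == role)

    @property
    def genome_ids(self) -> tuple[str, ...]:
        return tuple(self.assignments)

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self.assignments

    def __len__(self) -> int:
        return len(self.assignments)


def read_taxonomy(path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "clade", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"taxonomy table missing columns: {sorted(missing)}")
    dup = df["genome_id"][df["genome_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate genome ids in taxonomy: {sorted(set(dup))}")
    return TaxonomyMap(
        {r.genome_id: (r.clade, r.role) for r in df.itertuples(index=False)}
    )


def write_taxonomy(taxmap: TaxonomyMap, path) -> None:
    df = pd.DataFrame(
        [(g, c, r) for g, (c, r) in taxmap.assignments.items()],
        columns=["genome_id", "clade", "role"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_partitions(supermatrix) -> str:
    """Render a supermatrix partition map as ``marker = start-end`` lines.

    Coordinates are 1-based inclusive in concatenation order; markers whose
    columns were all dropped by the occupancy filter are omitted.
    """
    parts = getattr(supermatrix, "partitions", supermatrix)
    if not parts:
        raise ValueError("empty supermatrix: no partitions to write")
    lines = []
    for marker_id, (start, end) in parts.items():
        if end <= start:
            continue  # marker fully dropped by the occupancy filter
        lines.append(f"{marker_id} = {start + 1}-{end}")
    if not lines:
        raise ValueError("all partitions empty after filtering")
    return "\n".join(lines) + "\n"
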