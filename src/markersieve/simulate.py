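"""Synthetic phylogenomic data with known ground truth.

Emulates the study design downstream stages are tested against: a rooted
species tree with an outgroup, a TACK-like clade series (A), an
Asgard-like clade series (B) and a focal clade nested between them, plus
per-marker gene trees carrying controlled discordance — horizontal-
transfer-style prune-and-regraft events that move the focal clade into
one of the series, and contaminant events that relocate a single leaf —
and alignments evolved on those trees.  A :class:`TruthTable` records
every event so ranking and tendency classification can be scored against
ground truth.

The substitution process is deliberately plain (equal-rate 20-state
exchangeability, no rate heterogeneity): simulation only needs enough
signal for recovery tests, not the site-heterogeneous realism of real
archaeal data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

from .io import Alignment, TaxonomyMap, write_fasta, write_taxonomy
from .trees import GeneTree

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "TruthTable",
    "simulate_species_tree",
    "simulate_gene_trees",
    "evolve_alignment",
    "simulate_esp_hits",
    "synthetic_published_sets",
    "write_dataset",
]

AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationConfig:
    """Study-design knobs for the generator.

    Defaults sketch a small TACK/Asgard-like sampling: four clades per
    series, a two-genome focal clade (mirroring the two focal genomes
    placed in the study's trees) and a close outgroup.
    """

    n_clades_A: int = 4
    n_clades_B: int = 4
    taxa_per_clade: int = 4
    n_outgroup: int = 3
    focal_size: int = 2
    n_markers: int = 200
    hgt_rate: float = 0.25
    contaminant_rate: float = 0.05
    graft_target: str = "random"  # {"A", "B", "random"}
    jitter_sigma: float = 0.2
    aln_length: int = 200
    seed: int = 0

    def __post_init__(self):
        for name in ("n_clades_A", "n_clades_B", "taxa_per_clade", "n_outgroup",
                     "focal_size", "n_markers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("hgt_rate", "contaminant_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.graft_target not in ("A", "B", "random"):
            raise ValueError("graft_target must be 'A', 'B' or 'random'")


@dataclass(frozen=True)
class TruthRecord:
    marker_id: str
    clean: bool
    graft_group: str  # "A", "B" or "none"
    contaminant_leaf: Optional[str] = None

    def __post_init__(self):
        expect_clean = self.graft_group == "none" and self.contaminant_leaf is None
        if self.clean != expect_clean:
            raise ValueError("clean flag inconsistent with recorded events")


@dataclass
class TruthTable:
    records: dict[str, TruthRecord] = field(default_factory=dict)

    def __getitem__(self, marker_id: str) -> TruthRecord:
        return self.records[marker_id]

    def __len__(self) -> int:
        return len(self.records)

    def clean_ids(self) -> list[str]:
        return [m for m, r in self.records.items() if r.clean]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.marker_id, r.clean, r.graft_group, r.contaminant_leaf or "")
                for r in self.records.values()
            ],
            columns=["marker_id", "clean", "graft_group", "contaminant_leaf"],
        )


# ---------------------------------------------------------------------------
# species tree


def _ladder(parts: list[str], lengths: np.ndarray) -> str:
    """Fold newick substrings into a left ladder with given internal lengths."""
    out = parts[0]
    for i, p in enumerate(parts[1:]):
        out = f"({out},{p}):{lengths[i]:.6f}"
    return out


def _branch(rng: np.random.Generator) -> float:
    # lognormal around ~0.14 substitutions/site: short enough to keep
    # signal, long enough that splits are recoverable from short alignments
    return float(rng.lognormal(mean=-2.0, sigma=0.5))


def _clade_newick(leaf_names: list[str], rng: np.random.Generator) -> str:
    parts = [f"{n}:{_branch(rng):.6f}" for n in leaf_names]
    lens = np.array([_branch(rng) for _ in range(max(len(parts) - 1, 1))])
    return _ladder(parts, lens)


def simulate_species_tree(cfg: SimulationConfig) -> tuple[GeneTree, TaxonomyMap]:
    """Build the rooted reference topology and its taxonomy map.

    Shape: ``(outgroup, (A-series, (focal, B-series)))`` with every named
    clade monophyletic by construction and lognormal branch lengths.
    """
    rng = np.random.default_rng(cfg.seed)
    assignments: dict[str, tuple[str, str]] = {}

    def leaves(clade: str, k: int, role: str) -> list[str]:
        names = [f"{clade}_g{j + 1}" for j in range(k)]
        for n in names:
            assignments[n] = (clade, role)
        return names

    out_part = _clade_newick(leaves("OUT", cfg.n_outgroup, "outgroup"), rng)
    a_parts = [
        _clade_newick(leaves(f"A{i + 1}", cfg.taxa_per_clade, "ingroup"), rng)
        for i in range(cfg.n_clades_A)
    ]
    b_parts = [
        _clade_newick(leaves(f"B{i + 1}", cfg.taxa_per_clade, "ingroup"), rng)
        for i in range(cfg.n_clades_B)
    ]
    focal_part = _clade_newick(leaves("FOCAL", cfg.focal_size, "focal"), rng)

    a_series = _ladder(a_parts, np.array([_branch(rng) for _ in range(max(len(a_parts) - 1, 1))]))
    b_series = _ladder(b_parts, np.array([_branch(rng) for _ in range(max(len(b_parts) - 1, 1))]))
    inner = f"({focal_part},{b_series}):{_branch(rng):.6f}"
    ingroup = f"({a_series},{inner}):{_branch(rng):.6f}"
    newick = f"({out_part},{ingroup});"

    tree = GeneTree.from_newick(newick, marker_id="species")
    tree.tree.is_rooted = True
    return tree, TaxonomyMap(assignments)


# ---------------------------------------------------------------------------
# subtree prune and regraft plumbing (manual, to control tie-breaking)


def _detach(tree: dendropy.Tree, node: dendropy.Node) -> None:
    """Remove ``node``'s subtree, suppressing the unifurcation left behind."""
    parent = node.parent_node
    parent.remove_child(node)
    if parent.num_child_nodes() == 1:
        only = parent.child_nodes()[0]
        grand = parent.parent_node
        if grand is None:
            parent.remove_child(only)
            only.edge.length = None
            tree.seed_node = only
        else:
            merged = (parent.edge.length or 0.0) + (only.edge.length or 0.0)
            parent.remove_child(only)
            grand.remove_child(parent)
            grand.add_child(only)
            only.edge.length = merged


def _attach_on_edge(subtree: dendropy.Node, target: dendropy.Node,
                    insert_length: float) -> None:
    """Graft ``subtree`` by bisecting the edge above ``target``."""
    parent = target.parent_node
    L = target.edge.length or 0.0
    parent.remove_child(target)
    joint = dendropy.Node()
    parent.add_child(joint)
    joint.edge.length = L / 2.0
    joint.add_child(target)
    target.edge.length = L / 2.0
    joint.add_child(subtree)
    subtree.edge.length = insert_length


def _mrca(tree: dendropy.Tree, labels: frozenset[str]) -> dendropy.Node:
    taxa = [lf for lf in tree.leaf_node_iter() if lf.taxon.label in labels]
    return tree.mrca(taxa=[lf.taxon for lf in taxa])


def _nodes_within(
    tree: dendropy.Tree, labels: frozenset[str]
) -> list[tuple[dendropy.Node, frozenset]]:
    """Non-seed (node, leafset) pairs with subtree leaves wholly inside ``labels``."""
    out = []
    below: dict[dendropy.Node, frozenset] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = frozenset([nd.taxon.label])
        else:
            acc: frozenset = frozenset()
            for ch in nd.child_nodes():
                acc = acc | below[ch]
            below[nd] = acc
        if nd is not tree.seed_node and below[nd] <= labels:
            out.append((nd, below[nd]))
    return out


def _topological_distances(tree: dendropy.Tree, start: dendropy.Node) -> dict:
    """BFS node distances treating the tree as an undirected graph."""
    adj: dict[dendropy.Node, list[dendropy.Node]] = {}
    for nd in tree.preorder_node_iter():
        adj.setdefault(nd, [])
        for ch in nd.child_nodes():
            adj[nd].append(ch)
            adj.setdefault(ch, []).append(nd)
    dist = {start: 0}
    queue = [start]
    while queue:
        cur = queue.pop(0)
        for nb in adj[cur]:
            if nb not in dist:
                dist[nb] = dist[cur] + 1
                queue.append(nb)
    return dist


def _jitter_lengths(tree: dendropy.Tree, rng: np.random.Generator, sigma: float) -> None:
    for nd in tree.preorder_node_iter():
        if nd.edge.length is not None:
            nd.edge.length *= float(rng.lognormal(mean=0.0, sigma=sigma))


def simulate_gene_trees(
    species: GeneTree,
    taxmap: TaxonomyMap,
    cfg: SimulationConfig,
    graft_plan: Optional[Sequence[str]] = None,
) -> tuple[list[GeneTree], TruthTable]:
    """Derive per-marker gene trees from the species tree with known events.

    Each marker starts as a branch-length-jittered copy of the species
    tree.  With probability ``hgt_rate`` (or as dictated by an explicit
    ``graft_plan`` of per-marker ``"A"``/``"B"``/``"none"`` entries) the
    focal clade is pruned and regrafted onto a random edge inside the
    target series; with probability ``contaminant_rate`` one non-focal
    ingroup leaf is relocated to a random distant edge.  Leaf counts are
    preserved and every event is recorded in the truth table.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    focal = taxmap.genomes_with_role("focal")
    series: dict[str, frozenset[str]] = {}
    for grp, prefix in (("A", "A"), ("B", "B")):
        members = frozenset(
            g
            for g in taxmap.genome_ids
            if taxmap.role_of(g) == "ingroup" and taxmap.clade_of(g).startswith(prefix)
        )
        series[grp] = members
    movable = sorted(
        g for g in taxmap.genome_ids
        if taxmap.role_of(g) == "ingroup" and g in species.leaf_set
    )
    if graft_plan is not None and len(graft_plan) != cfg.n_markers:
        raise ValueError("graft_plan length must equal n_markers")

    trees: list[GeneTree] = []
    truth = TruthTable()
    for i in range(cfg.n_markers):
        marker_id = f"m{i + 1:04d}"
        gt = species.clone()
        gt.marker_id = marker_id
        _jitter_lengths(gt.tree, rng, cfg.jitter_sigma)

        if graft_plan is not None:
            target = graft_plan[i]
        elif rng.random() < cfg.hgt_rate:
            target = cfg.graft_target
            if target == "random":
                target = "A" if rng.random() < 0.5 else "B"
        else:
            target = "none"

        if target != "none":
            if not series[target]:
                raise ValueError(f"graft target series {target!r} is empty")
            focal_node = _mrca(gt.tree, focal)
            parent = focal_node.parent_node
            sets_before = {}
            for nd in gt.tree.postorder_node_iter():
                sets_before[nd] = (
                    frozenset([nd.taxon.label]) if nd.is_leaf()
                    else frozenset().union(*(sets_before[c] for c in nd.child_nodes()))
                )
            original_sister = sets_before[parent] - sets_before[focal_node]
            _detach(gt.tree, focal_node)
            # skip the regraft position that would recreate the original
            # attachment: the event must actually change the topology
            candidates = [
                nd for nd, leafset in _nodes_within(gt.tree, series[target])
                if leafset != original_sister
            ]
            if not candidates:
                raise ValueError(f"no regraft edge available in series {target!r}")
            choice = candidates[int(rng.integers(len(candidates)))]
            _attach_on_edge(focal_node, choice, insert_length=_branch(rng))

        contaminant = None
        if rng.random() < cfg.contaminant_rate:
            leaf_label = movable[int(rng.integers(len(movable)))]
            leaf = next(
                lf for lf in gt.tree.leaf_node_iter() if lf.taxon.label == leaf_label
            )
            origin = leaf.parent_node
            # remember surviving neighborhood: origin may be suppressed away
            anchors = [c for c in origin.child_nodes() if c is not leaf]
            if origin.parent_node is not None:
                anchors.append(origin.parent_node)
            _detach(gt.tree, leaf)
            still = set(gt.tree.preorder_node_iter())
            start = next((a for a in anchors if a in still), gt.tree.seed_node)
            dist = _topological_distances(gt.tree, start)
            far = [
                nd
                for nd in gt.tree.preorder_node_iter()
                if nd is not gt.tree.seed_node and dist.get(nd, 0) > 3
            ]
            if far:
                choice = far[int(rng.integers(len(far)))]
                _attach_on_edge(leaf, choice, insert_length=_branch(rng))
                contaminant = leaf_label
            else:  # tree too small for a "distant" edge: reattach locally
                target = start if start is not gt.tree.seed_node \
                    else start.child_nodes()[0]
                _attach_on_edge(leaf, target, insert_length=_branch(rng))

        truth.records[marker_id] = TruthRecord(
            marker_id=marker_id,
            clean=(target == "none" and contaminant is None),
            graft_group=target,
            contaminant_leaf=contaminant,
        )
        trees.append(gt)
    return trees, truth


# ---------------------------------------------------------------------------
# sequence evolution


def evolve_alignment(tree: GeneTree, length: int, seed: int) -> Alignment:
    """Evolve an amino-acid alignment down a tree.

    Equal-exchangeability 20-state model scaled to one expected
    substitution per unit branch length; the probability that a site
    differs after time t is (19/20)(1 - exp(-20t/19)).  Root sequence
    drawn from the uniform stationary distribution.
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 20, size=length)
    seqs: dict = {tree.tree.seed_node: root_seq}
    rows: dict[str, str] = {}
    for nd in tree.tree.preorder_node_iter():
        if nd is tree.tree.seed_node:
            pass
        else:
            t = nd.edge.length or 0.0
            parent_seq = seqs[nd.parent_node]
            p_diff = (19.0 / 20.0) * (1.0 - np.exp(-20.0 * t / 19.0))
            mask = rng.random(length) < p_diff
            child = parent_seq.copy()
            # jump to one of the 19 other states, uniformly
            child[mask] = (child[mask] + 1 + rng.integers(0, 19, size=int(mask.sum()))) % 20
            seqs[nd] = child
        if nd.is_leaf():
            rows[nd.taxon.label] = "".join(AA[k] for k in seqs[nd])
    ordered = {g: rows[g] for g in sorted(rows)}
    return Alignment(marker_id=tree.marker_id, rows=ordered)


# ---------------------------------------------------------------------------
# ESP-style presence/absence hits


def simulate_esp_hits(
    taxmap: TaxonomyMap,
    n_core: int = 6,
    n_rich: int = 10,
    n_poor: int = 4,
    flip_rate: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Hit table emulating eukaryote-signature-protein distributions.

    Core families occur in every genome; a rich family set marks the
    B-series plus the focal clade (the Asgard-like ESP complement) and a
    smaller set marks the A-series; ``flip_rate`` adds presence/absence
    noise.  Returns rows (genome_id, family_id, n_copies).
    """
    rng = np.random.default_rng(seed)
    fams_core = [f"ESP_core{i + 1}" for i in range(n_core)]
    fams_rich = [f"ESP_asg{i + 1}" for i in range(n_rich)]
    fams_poor = [f"ESP_tack{i + 1}" for i in range(n_poor)]
    rows = []
    for g in taxmap.genome_ids:
        clade, role = taxmap.assignments[g]
        present = set(fams_core)
        if role == "focal" or (role == "ingroup" and clade.startswith("B")):
            present |= set(fams_rich)
        elif role == "ingroup" and clade.startswith("A"):
            present |= set(fams_poor)
        for fam in fams_core + fams_rich + fams_poor:
            has = fam in present
            if rng.random() < flip_rate:
                has = not has
            if has:
                rows.append((g, fam, 1))
    return pd.DataFrame(rows, columns=["genome_id", "family_id", "n_copies"])


# ---------------------------------------------------------------------------
# synthetic stand-in for the deposited marker catalog


def synthetic_published_sets() -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Synthetic stand-in for the deposited supplementary marker table.

    The real catalog (a FigShare deposit of marker accessions from seven
    earlier phylogenomic studies) is not bundled; this deterministic
    surrogate mirrors its published structure so the pooling machinery
    can be exercised end to end: seven source sets whose nonredundant
    union is 248 markers, 12 of them from the asCOG namespace, and four
    ranked selections — undin28/undin56 (top 25%/50% of an earlier
    ranking) and tacka60/tacka120 (this workflow's top 25%/50%) — of
    sizes 28/56/60/120 sharing a 19-marker four-way core, with 3 and 6
    asCOGs inside tacka60 and tacka120 respectively.

    Returns (source_sets, selections); all ids are synthetic accessions.
    """
    ascog_slots = {56, 57, 58, 97, 98, 99, 157, 158, 159, 160, 161, 162}
    ids: list[str] = []
    n_as = 0
    n_ar = 0
    for i in range(248):
        if i in ascog_slots:
            n_as += 1
            ids.append(f"asCOG{n_as:05d}")
        else:
            n_ar += 1
            ids.append(f"arCOG{n_ar:05d}")

    source_sets = {
        "ribo_universal": ids[0:120],
        "gtdb_ar122": ids[60:180],
        "phylosift": ids[150:248],
        "rp56": ids[0:40] + ids[200:230],
        "cog_core": ids[30:90],
        "tigr_archaeal": ids[100:140],
        "asCOG": [ids[i] for i in sorted(ascog_slots)],
    }
    # spike in version suffixes / case variants the normalizer must fold
    source_sets["rp56"] = [a + ".1" if i % 7 == 0 else a for i, a in enumerate(source_sets["rp56"])]
    source_sets["cog_core"] = [a.lower() if i % 5 == 0 else a for i, a in enumerate(source_sets["cog_core"])]

    tacka60 = ids[0:19] + ids[56:97]
    tacka120 = tacka60 + ids[97:157]
    selections = {
        "undin28": ids[0:28],
        "undin56": ids[0:56],
        "tacka60": tacka60,
        "tacka120": tacka120,
    }
    return source_sets, selections


# ---------------------------------------------------------------------------
# dataset writer


def write_dataset(outdir, cfg: SimulationConfig) -> dict:
    """Simulate a full dataset and write it as plain-text files.

    Layout: species.nwk, markers/*.nwk, alignments/*.fasta, taxonomy.tsv,
    truth.tsv, esp_hits.tsv, config.yaml.  Byte-identical for identical
    (config, seed).
    """
    outdir = Path(outdir)
    (outdir / "markers").mkdir(parents=True, exist_ok=True)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)

    species, taxmap = simulate_species_tree(cfg)
    gene_trees, truth = simulate_gene_trees(species, taxmap, cfg)

    (outdir / "species.nwk").write_text(species.to_newick())
    write_taxonomy(taxmap, outdir / "taxonomy.tsv")
    rng = np.random.default_rng(cfg.seed + 2)
    for gt in gene_trees:
        (outdir / "markers" / f"{gt.marker_id}.nwk").write_text(gt.to_newick())
        aln = evolve_alignment(gt, cfg.aln_length, seed=int(rng.integers(2**31)))
        write_fasta(aln, outdir / "alignments" / f"{gt.marker_id}.fasta")
    truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    simulate_esp_hits(taxmap, seed=cfg.seed + 3).to_csv(
        outdir / "esp_hits.tsv", sep="\t", index=False
    )
    (outdir / "config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(cfg)))
    return {
        "n_markers": len(gene_trees),
        "n_genomes": len(taxmap),
        "n_clean": len(truth.clean_ids()),
    }
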