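"""End-to-end orchestration: simulate/load -> pool -> score -> rank ->
concat -> tendency -> venn -> esp, with a manifest and resumability.

Every stage reads its inputs from and writes its outputs to the run
directory, so a rerun with ``resume=True`` recomputes only stages whose
outputs are missing or stale.  With a fixed config and seed the output
files are byte-identical between runs (the manifest's wall times are the
only nondeterministic artifact).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import congruence, esp, markers, simulate, supermatrix, tendency
from .io import read_taxonomy, write_fasta, write_partitions
from .trees import read_newick_file

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ["simulate", "pool", "score", "rank", "concat", "tendency", "venn", "esp"]


@dataclass
class PipelineConfig:
    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig
    )
    top_fractions: tuple[float, ...] = (0.25, 0.5)
    k_overrides: dict[str, int] = field(default_factory=dict)
    occupancy_threshold: float = 0.6
    focal_clade: str = "FOCAL"
    groupsA: Optional[tuple[str, ...]] = None  # default: clades named A*
    groupsB: Optional[tuple[str, ...]] = None  # default: clades named B*
    seed: int = 0

    def __post_init__(self):
        fr = tuple(self.top_fractions)
        if list(fr) != sorted(fr):
            raise ValueError("top_fractions must be sorted ascending")
        if not (0.0 < self.occupancy_threshold <= 1.0):
            raise ValueError("occupancy_threshold must lie in (0, 1]")
        self.top_fractions = fr

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = simulate.SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["top_fractions"] = list(self.top_fractions)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _frac_tag(frac: float) -> str:
    return f"top{int(round(frac * 100))}"


def run_pipeline(cfg: PipelineConfig, outdir, resume: bool = False) -> dict:
    """Run all stages, returning the manifest (also written as manifest.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_dir = outdir / "simulate"

    sel_paths = [outdir / f"selection_{_frac_tag(f)}.tsv" for f in cfg.top_fractions]
    stage_outputs: dict[str, list[Path]] = {
        "simulate": [sim_dir / "species.nwk", sim_dir / "taxonomy.tsv",
                     sim_dir / "truth.tsv", sim_dir / "esp_hits.tsv"],
        "pool": [outdir / "catalog.tsv"],
        "score": [outdir / "scores.tsv"],
        "rank": sel_paths,
        "concat": [outdir / "supermatrix.fasta", outdir / "partitions.txt",
                   outdir / "occupancy.tsv"],
        "tendency": [outdir / "tendency.tsv"],
        "venn": [outdir / "venn.tsv"],
        "esp": [outdir / "esp_matrix.tsv", outdir / "esp_dendrogram.nwk"],
    }

    manifest: dict = {"config": cfg.to_dict(), "stages": []}
    dirty = False  # once a stage runs, everything downstream reruns

    def stage_done(name: str) -> bool:
        return all(p.exists() for p in stage_outputs[name])

    def record(name: str, status: str, t0: float, counts: dict) -> None:
        entry = {
            "stage": name,
            "status": status,
            "wall_time_s": round(time.monotonic() - t0, 4),
            "outputs": {
                str(p.relative_to(outdir)): _sha256(p)
                for p in stage_outputs[name] if p.exists()
            },
            "counts": counts,
        }
        manifest["stages"].append(entry)

    def log(name: str, **counts) -> None:
        kv = " ".join(f"{k}={v}" for k, v in counts.items())
        print(f"[markersieve] stage={name} {kv}")

    try:
        for name in STAGES:
            t0 = time.monotonic()
            if resume and not dirty and stage_done(name):
                record(name, "cached", t0, {})
                continue
            dirty = True
            counts = _run_stage(name, cfg, outdir, sim_dir)
            log(name, **counts)
            record(name, "completed", t0, counts)
    except Exception:
        manifest["failed_stage"] = name
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _load_trees(sim_dir: Path) -> list:
    return [
        read_newick_file(p, marker_id=p.stem)
        for p in sorted((sim_dir / "markers").glob("*.nwk"))
    ]


def _groups(cfg: PipelineConfig, taxmap) -> tuple[tuple[str, ...], tuple[str, ...]]:
    ga = cfg.groupsA or tuple(c for c in taxmap.clades() if c.startswith("A"))
    gb = cfg.groupsB or tuple(c for c in taxmap.clades() if c.startswith("B"))
    return ga, gb


def _run_stage(name: str, cfg: PipelineConfig, outdir: Path, sim_dir: Path) -> dict:
    if name == "simulate":
        sim_cfg = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        info = simulate.write_dataset(sim_dir, sim_cfg)
        return {"markers": info["n_markers"], "genomes": info["n_genomes"],
                "clean": info["n_clean"]}

    if name == "pool":
        ids = sorted(p.stem for p in (sim_dir / "markers").glob("*.nwk"))
        cut = 2 * len(ids) // 3
        cat = markers.dereplicate({"sim_a": ids[:cut], "sim_b": ids[len(ids) - cut:]})
        cat.write_tsv(outdir / "catalog.tsv")
        return {"markers_in": 2 * cut, "markers_out": len(cat)}

    taxmap = read_taxonomy(sim_dir / "taxonomy.tsv")

    if name == "score":
        clades = congruence.clades_from_taxonomy(taxmap)
        scores = [congruence.score_marker(t, clades) for t in _load_trees(sim_dir)]
        congruence.scores_to_frame(scores).to_csv(
            outdir / "scores.tsv", sep="\t", index=False
        )
        return {"markers": len(scores), "clades": len(clades)}

    if name == "rank":
        df = pd.read_csv(outdir / "scores.tsv", sep="\t")
        scores = [
            congruence.CongruenceScore(r.marker_id, int(r.n_evaluable),
                                       int(r.n_monophyletic))
            for r in df.itertuples(index=False)
        ]
        counts = {}
        for frac in cfg.top_fractions:
            tag = _frac_tag(frac)
            sel = congruence.rank_and_select(
                scores, frac, k_override=cfg.k_overrides.get(tag)
            )
            pd.DataFrame({"marker_id": sel.selected}).to_csv(
                outdir / f"selection_{tag}.tsv", sep="\t", index=False
            )
            counts[tag] = len(sel.selected)
        return counts

    if name == "concat":
        from .io import read_fasta

        alns = [
            read_fasta(p) for p in sorted((sim_dir / "alignments").glob("*.fasta"))
        ]
        sm = supermatrix.concatenate(
            alns, taxa=sorted(taxmap.genome_ids), threshold=cfg.occupancy_threshold
        )
        write_fasta(sm.to_alignment(), outdir / "supermatrix.fasta")
        (outdir / "partitions.txt").write_text(write_partitions(sm))
        sm.marker_summary().to_csv(outdir / "occupancy.tsv", sep="\t", index=False)
        return {"columns_kept": sm.n_columns_kept,
                "columns_dropped": sm.n_columns_dropped}

    if name == "tendency":
        ga, gb = _groups(cfg, taxmap)
        table = tendency.classify_all(_load_trees(sim_dir), taxmap, ga, gb)
        table.to_frame().to_csv(outdir / "tendency.tsv", sep="\t", index=False)
        labels = table.to_frame()["label"].value_counts().to_dict()
        return {k: int(v) for k, v in labels.items()}

    if name == "venn":
        table = tendency.TendencyTable()
        df = pd.read_csv(outdir / "tendency.tsv", sep="\t")
        for r in df.itertuples(index=False):
            table.add(tendency.TendencyRow(
                r.marker_id, tendency.TendencyLabel(r.label),
                bool(r.focal_monophyletic),
            ))
        sets = {}
        for frac in cfg.top_fractions:
            tag = _frac_tag(frac)
            sel = pd.read_csv(outdir / f"selection_{tag}.tsv", sep="\t")
            sets[tag] = list(sel["marker_id"])
        report = tendency.venn_overlap(sets, table)
        report.to_frame().to_csv(outdir / "venn.tsv", sep="\t", index=False)
        return {"regions": len(report.regions)}

    if name == "esp":
        hits = markers.read_hit_table(sim_dir / "esp_hits.tsv")
        fams = sorted(set(hits["family_id"]))
        mat = esp.build_matrix(hits, families=fams)
        mat.to_frame().to_csv(outdir / "esp_matrix.tsv", sep="\t")
        dend = esp.upgma(esp.profile_distance(mat), labels=mat.genomes)
        (outdir / "esp_dendrogram.nwk").write_text(dend.newick + "\n")
        return {"genomes": len(mat.genomes), "families": len(fams)}

    raise ValueError(f"unknown stage {name!r}")
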