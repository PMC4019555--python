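"""Orchestrate all analysis stages as one reproducible run.

Stages are independent after the genome/annotation is loaded; any stage
failure is recorded in the manifest and the remaining stages continue.  The
manifest lists every artifact with its sha256 and the parameters that
produced it, so identical config + inputs yield identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import codon_phylo, repeats, skew, structure_stats, trna_he
from . import genome_io as gio

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Fully serializable run description; a run is reproducible from the
    config plus its input files alone."""

    genome: str  # FASTA path
    annotation: str | None = None  # GFF3 path
    out_dir: str = "mitofeatures_out"
    seed: int = 0
    code_table: int = 4
    skew_params: dict = field(default_factory=lambda: {"window_bp": 1000, "step_bp": 100})
    repeat_params: dict = field(
        default_factory=lambda: {"seed_k": 11, "min_len": 30, "min_identity": 0.75}
    )
    duplication_params: dict = field(default_factory=lambda: {"min_len": 1000})
    cluster_cutoffs: tuple = (0.75, 0.80, 0.90)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["cluster_cutoffs"] = list(self.cluster_cutoffs)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict[str, Any]:
    """Run every stage, write TSV/JSON/newick artifacts, return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": {**dataclasses.asdict(config), "cluster_cutoffs": list(config.cluster_cutoffs)},
        "stages": {},
        "outputs": {},
    }

    genome = gio.read_fasta_genome(config.genome)
    genes: list[gio.GeneModel] = []
    anticodons: list[gio.AnticodonRecord] = []
    if config.annotation:
        _, genes, anticodons = gio.read_annotated_genome(
            config.annotation, "gff3+fasta", fasta_path=config.genome
        )

    def record(stage: str, status: str, note: str = "", files: list[Path] = ()) -> None:
        manifest["stages"][stage] = {"status": status, "note": note}
        for f in files:
            manifest["outputs"][str(f.relative_to(out))] = _sha256(f)

    # --- gene structure + composition --------------------------------------
    try:
        if not genes:
            record("structure", "skipped", "no annotation provided")
        else:
            rows = [dataclasses.asdict(structure_stats.gene_structure(g, len(genome)))
                    for g in genes]
            f1 = out / "gene_structure.tsv"
            pd.DataFrame(rows).to_csv(f1, sep="\t", index=False)
            comp = structure_stats.genome_composition(genome, genes)
            f2 = out / "composition.tsv"
            pd.DataFrame([
                {"category": k, "bp": getattr(comp, f"{k}_bp"), "fraction": v}
                for k, v in comp.fractions.items()
            ]).to_csv(f2, sep="\t", index=False)
            record("structure", "ok", files=[f1, f2])
    except Exception as exc:  # noqa: BLE001 - independent stages continue
        record("structure", "failed", repr(exc))

    # --- codon usage --------------------------------------------------------
    try:
        protein_genes = [g for g in genes if g.feature_class == "protein"]
        if not protein_genes:
            record("codon_usage", "skipped", "no protein genes")
        else:
            cds = ["".join(genome.fetch(e) for e in g.exons) for g in protein_genes]
            usage = codon_phylo.count_codons(cds, taxon=genome.id)
            f = out / "codon_usage.tsv"
            pd.DataFrame(
                sorted(usage.counts.items()), columns=["codon", "count"]
            ).to_csv(f, sep="\t", index=False)
            gc_all, gc1, gc2, gc3 = codon_phylo.positional_gc(cds)
            f2 = out / "codon_gc.json"
            f2.write_text(json.dumps(
                {"overall": gc_all, "gc1": gc1, "gc2": gc2, "gc3": gc3}, indent=2))
            record("codon_usage", "ok", files=[f, f2])
    except Exception as exc:  # noqa: BLE001
        record("codon_usage", "failed", repr(exc))

    # --- skew ---------------------------------------------------------------
    try:
        profile = skew.windowed_skew(genome, **config.skew_params)
        at_profile = skew.windowed_skew(genome, pair="AT", **{
            k: v for k, v in config.skew_params.items() if k != "pair"})
        f = out / "skew.tsv"
        pd.DataFrame({
            "position": profile.positions.astype(int),
            "gc_skew": profile.values,
            "at_skew": at_profile.values,
        }).to_csv(f, sep="\t", index=False, float_format="%.6f")
        landmarks = skew.call_replication_landmarks(profile, seed=config.seed)
        f2 = out / "replication_landmarks.json"
        f2.write_text(json.dumps(dataclasses.asdict(landmarks), indent=2))
        record("skew", "ok",
               "" if landmarks.called else "no-call: skew indistinguishable from null",
               files=[f, f2])
    except Exception as exc:  # noqa: BLE001
        record("skew", "failed", repr(exc))

    # --- repeats ------------------------------------------------------------
    try:
        pairs = repeats.self_compare(genome, **config.repeat_params)
        f = out / "repeats.tsv"
        pd.DataFrame([
            {
                "a_start": p.interval_a.start, "a_end": p.interval_a.end,
                "b_start": p.interval_b.start, "b_end": p.interval_b.end,
                "orientation": p.orientation, "identity": round(p.identity, 4),
                "length": p.length, "evalue_like": p.score,
            }
            for p in pairs
        ]).to_csv(f, sep="\t", index=False)
        clusters = repeats.cluster_repeats(pairs, genome, config.cluster_cutoffs)
        f2 = out / "repeat_clusters.tsv"
        rows = []
        for cutoff, cls in clusters.items():
            for ci, cl in enumerate(cls):
                for iv in cl.members:
                    rows.append({"cutoff": cutoff, "cluster": ci,
                                 "start": iv.start, "end": iv.end})
        pd.DataFrame(rows).to_csv(f2, sep="\t", index=False)
        files = [f, f2]
        if genes:
            cov = repeats.repeat_coverage(pairs, genes, genome)
            f3 = out / "repeat_coverage.json"
            f3.write_text(json.dumps(dataclasses.asdict(cov), indent=2))
            files.append(f3)
        dups = repeats.find_inverted_duplication(genome, **config.duplication_params)
        f4 = out / "inverted_duplication.json"
        f4.write_text(json.dumps([
            {
                "region_1": [d.region_1.start, d.region_1.end],
                "region_2": [d.region_2.start, d.region_2.end],
                "length": d.length, "identity": round(d.identity, 6),
                "mismatches": [
                    [m.position, m.base_1, m.base_2, m.kind] for m in d.mismatches
                ],
            }
            for d in dups
        ], indent=2))
        files.append(f4)
        record("repeats", "ok", files=files)
    except Exception as exc:  # noqa: BLE001
        record("repeats", "failed", repr(exc))

    # --- decoding -----------------------------------------------------------
    try:
        if not anticodons:
            record("decoding", "skipped", "annotation lacks tRNAs")
        else:
            protein_genes = [g for g in genes if g.feature_class == "protein"]
            cds = ["".join(genome.fetch(e) for e in g.exons) for g in protein_genes]
            usage = codon_phylo.count_codons(cds, taxon=genome.id)
            report = trna_he.decoding_check(
                anticodons, usage, code_table=config.code_table
            )
            f = out / "decoding_report.json"
            f.write_text(json.dumps({
                "sufficient": report.sufficient,
                "decodable": sorted(report.decodable),
                "undecodable": sorted(report.undecodable),
                "undecodable_used": report.undecodable_used,
                "unassigned_candidates": report.unassigned_candidates,
                "notes": report.notes,
            }, indent=2))
            record("decoding", "ok", files=[f])
    except Exception as exc:  # noqa: BLE001
        record("decoding", "failed", repr(exc))

    mf = out / "manifest.json"
    mf.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
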