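"""End-to-end orchestration: scan -> classify -> compare -> summarize.

Stage outputs are plain GFF3/TSV/JSON with fully deterministic ordering, so a
rerun with the same inputs, seed and configuration is byte-identical. The run
log records the configuration hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from pheroscan.compare import (pairwise_identity, read_strategy_table,
                               summarize_by_strategy, unique_peptides)
from pheroscan.config import PipelineConfig
from pheroscan.pheromone_a import APheromoneCall, scan_genome_for_a_pheromones
from pheroscan.pheromone_alpha import call_alpha_pheromone
from pheroscan.receptor import classify_receptor
from pheroscan.seqio import GffFeature, SequenceRecord, read_fasta, write_gff3

logger = logging.getLogger(__name__)


@dataclass
class Manifest:
    """Input file paths for a full run; every entry is optional."""

    genome: Path | None = None
    alpha_proteins: Path | None = None
    receptor_proteins: Path | None = None
    strategies: Path | None = None
    features: Path | None = None   # per-species feature table for the cross-tab

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Manifest":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        valid = {"genome", "alpha_proteins", "receptor_proteins", "strategies",
                 "features"}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown manifest key(s): {sorted(unknown)}")
        base = Path(path).parent
        kwargs = {k: (base / v if not Path(v).is_absolute() else Path(v))
                  for k, v in data.items() if v}
        for key, p in kwargs.items():
            if not p.exists():
                raise FileNotFoundError(f"manifest entry {key!r}: {p} does not exist")
        return cls(**kwargs)


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def a_call_gene_id(call: APheromoneCall) -> str:
    stop = call.cds_start if call.strand == "-" else call.cds_end - 3
    return f"{call.contig}:{call.strand}:{stop}"


def a_calls_to_gff(calls: list[APheromoneCall],
                   contig_lengths: dict[str, int]) -> list[GffFeature]:
    feats = []
    for call in calls:
        feats.append(GffFeature(
            contig=call.contig, start=call.cds_start, end=call.cds_end,
            strand=call.strand, type="pheromone_gene",
            feature_id=a_call_gene_id(call),
            attributes={"verdict": call.verdict,
                        "n_mature_peptides": str(len(call.mature_peptides))},
        ))
    return feats


def write_a_peptides_tsv(calls: list[APheromoneCall], path: Path) -> None:
    rows = []
    for call in calls:
        for pep in call.mature_peptides:
            rows.append({
                "contig": call.contig, "gene_id": a_call_gene_id(call),
                "peptide": pep.sequence, "length": pep.length,
                "motif_kind": pep.motif_kind,
                "support": f"{pep.support:.4f}",
            })
    pd.DataFrame(rows, columns=["contig", "gene_id", "peptide", "length",
                                "motif_kind", "support"]).to_csv(
        path, sep="\t", index=False)


def scan_a_stage(genome: Path, outdir: Path,
                 cfg: PipelineConfig) -> list[APheromoneCall]:
    records = read_fasta(genome, "dna")
    calls = scan_genome_for_a_pheromones(records, cfg)
    lengths = {r.id: len(r.seq) for r in records}
    write_gff3(a_calls_to_gff(calls, lengths), outdir / "a_calls.gff3", lengths)
    write_a_peptides_tsv(calls, outdir / "a_peptides.tsv")
    return calls


def scan_alpha_stage(proteins: Path, outdir: Path, cfg: PipelineConfig):
    records = read_fasta(proteins, "protein")
    calls = [call_alpha_pheromone(rec, cfg) for rec in records]
    rows = []
    for call in calls:
        base = {"protein_id": call.protein_id, "verdict": call.verdict,
                "n_sites": len(call.sites),
                "n_peptides": len(call.mature_peptides)}
        if not call.mature_peptides:
            rows.append({**base, "peptide": "", "span": "", "central": "",
                         "turn": ""})
        for pep in call.mature_peptides:
            rows.append({**base, "peptide": pep.sequence,
                         "span": f"{pep.start}-{pep.end}",
                         "central": pep.sequence[len(pep.sequence) // 2],
                         "turn": "yes"})
    pd.DataFrame(rows, columns=["protein_id", "verdict", "n_sites",
                                "n_peptides", "peptide", "span", "central",
                                "turn"]).to_csv(
        outdir / "alpha_calls.tsv", sep="\t", index=False)
    return calls


def classify_receptor_stage(proteins: Path, outdir: Path, cfg: PipelineConfig):
    records = read_fasta(proteins, "protein")
    calls = [classify_receptor(rec, cfg) for rec in records]
    rows = [{
        "protein_id": c.protein_id, "n_tm": c.n_tm,
        "segments": ";".join(f"{s.start}-{s.end}" for s in c.tm_segments),
        "c_terminus": c.c_terminus, "functional": str(c.functional).lower(),
        "length": c.length,
    } for c in calls]
    pd.DataFrame(rows, columns=["protein_id", "n_tm", "segments", "c_terminus",
                                "functional", "length"]).to_csv(
        outdir / "receptors.tsv", sep="\t", index=False)
    return calls


def compare_stage(peptide_records: list[SequenceRecord], outdir: Path,
                  cfg: PipelineConfig, prefix: str = "peptide"):
    if len(peptide_records) >= 2:
        matrix = pairwise_identity(peptide_records, cfg.align)
        matrix.to_frame().round(2).to_csv(outdir / f"{prefix}_identity.tsv", sep="\t")
    census, n_distinct = unique_peptides([r.seq for r in peptide_records])
    pd.DataFrame(
        [{"peptide": seq, "count": count} for seq, count in census.items()],
        columns=["peptide", "count"],
    ).to_csv(outdir / f"{prefix}_census.tsv", sep="\t", index=False)
    return census, n_distinct


def run_pipeline(manifest: Manifest, cfg: PipelineConfig,
                 outdir: str | Path) -> dict:
    """Run every stage for which the manifest provides inputs.

    Writes stage outputs plus ``summary.json`` and ``run.log`` into
    ``outdir``; returns the summary dict. A stage failure aborts the run with
    the failing stage named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config_hash(cfg), "seed": cfg.seed}
    log_lines = [f"config_hash={config_hash(cfg)}", f"seed={cfg.seed}"]

    def stage(name, fn, *args):
        log_lines.append(f"stage={name} status=start")
        try:
            result = fn(*args)
        except Exception as exc:
            log_lines.append(f"stage={name} status=failed error={exc}")
            (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log_lines.append(f"stage={name} status=done")
        return result

    peptide_records: list[SequenceRecord] = []
    if manifest.genome is not None:
        a_calls = stage("scan-a", scan_a_stage, manifest.genome, outdir, cfg)
        functional = [c for c in a_calls if c.functional]
        summary["a_pheromone"] = {
            "n_calls": len(a_calls),
            "n_putatively_functional": len(functional),
            "n_mature_peptides": sum(len(c.mature_peptides) for c in functional),
        }
        for call in functional:
            for k, pep in enumerate(call.mature_peptides):
                peptide_records.append(SequenceRecord(
                    id=f"{a_call_gene_id(call)}|pep{k}", seq=pep.sequence,
                    alphabet="protein"))
    if manifest.alpha_proteins is not None:
        alpha_calls = stage("scan-alpha", scan_alpha_stage,
                            manifest.alpha_proteins, outdir, cfg)
        functional = [c for c in alpha_calls if c.functional]
        summary["alpha_pheromone"] = {
            "n_calls": len(alpha_calls),
            "n_putatively_functional": len(functional),
            "n_mature_peptides": sum(len(c.mature_peptides) for c in functional),
        }
        for call in functional:
            for k, pep in enumerate(call.mature_peptides):
                peptide_records.append(SequenceRecord(
                    id=f"{call.protein_id}|pep{k}", seq=pep.sequence,
                    alphabet="protein"))
    if manifest.receptor_proteins is not None:
        receptor_calls = stage("classify-receptor", classify_receptor_stage,
                               manifest.receptor_proteins, outdir, cfg)
        summary["receptors"] = {
            "n_candidates": len(receptor_calls),
            "n_functional": sum(c.functional for c in receptor_calls),
        }
    if peptide_records:
        census, n_distinct = stage("compare", compare_stage, peptide_records,
                                   outdir, cfg)
        summary["peptides"] = {"n_total": int(sum(census.values())),
                               "n_distinct": n_distinct}
    if manifest.strategies is not None and manifest.features is not None:
        strategies = read_strategy_table(manifest.strategies)
        features = pd.read_csv(manifest.features, sep="\t")
        table = stage("strategy-summary", summarize_by_strategy, features,
                      strategies)
        flat = table.copy()
        flat.columns = ["_".join(col) for col in flat.columns]
        flat.to_csv(outdir / "strategy_summary.tsv", sep="\t")
        summary["strategies"] = {"n_species": len(strategies),
                                 "n_strategies": len(set(strategies.values()))}
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
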