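"""End-to-end orchestration: simulate -> map -> call -> screen -> copy number.

One config plus one seed drives every stage; all intermediates are plain
files (FASTA/FASTQ/SAM/TSV/JSON) written into the output directory, and
a rerun with the same config and seed is byte-identical.  Stage seeds
are derived from the run seed through a seed sequence so the stages stay
independent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import copynum as cn
from . import samio, svdiscover
from .adjacency import Adjacency, format_adjacency, match_adjacency
from .align import InsertModel, KmerIndex, map_pairs
from .genome import (
    GenomeConfig,
    GenomeModel,
    apply_insertion,
    build_reference,
    default_construct,
    write_annotation_bed,
    write_fasta,
    write_truth_json,
)
from .simreads import SimConfig, simulate_reads, write_fastq_pair

log = logging.getLogger("tglocus.pipeline")


@dataclass(frozen=True)
class RunConfig:
    """Composite configuration for a full in-silico discovery run."""

    genome: GenomeConfig = field(default_factory=GenomeConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    tandem_copies: int = 1
    inverted_tail: bool = True
    deleted_span: int = 0
    min_support: int = 4
    roi_margin: int = 5_000
    seed: int = 0

    @property
    def insert_model(self) -> InsertModel:
        return InsertModel(mean=self.sim.insert_mean, sd=self.sim.insert_sd)

    @property
    def roi(self) -> tuple[str, int, int]:
        lo, hi = self.genome.bac_interval
        return (self.genome.donor_chrom, max(1, lo - self.roi_margin), hi + self.roi_margin)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        genome = GenomeConfig(**raw.pop("genome", {}))
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(genome=genome, sim=sim, **raw)


@dataclass
class RunReport:
    """Summary of one run: calls vs truth, copy estimates vs truth."""

    parameters: dict
    called_adjacencies: list[str]
    truth_adjacencies: list[str]
    truth_recovered: int
    false_positives: int
    copy_estimates: dict[str, float]
    truth_copy_number: dict[str, int]
    file_checksums: dict[str, str]

    def as_dict(self) -> dict:
        return asdict(self)


def _stage_seeds(seed: int, n: int = 3) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _md5(path: Path) -> str:
    h = hashlib.md5()
    h.update(path.read_bytes())
    return h.hexdigest()


def build_model(cfg: RunConfig) -> GenomeModel:
    """Genome + insertion for a run config (stage 1)."""
    genome_seed, cre_seed, _ = _stage_seeds(cfg.seed)
    wild = build_reference(cfg.genome, genome_seed)
    construct = default_construct(
        cfg.genome, cre_seed, tandem_copies=cfg.tandem_copies, inverted_tail=cfg.inverted_tail
    )
    return apply_insertion(wild, construct, deleted_span=cfg.deleted_span)


def run_all(cfg: RunConfig, outdir: str | Path) -> RunReport:
    """Execute every stage, writing intermediates under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _, _, read_seed = _stage_seeds(cfg.seed)

    log.info("stage genome: seed=%d chrom_length=%d", cfg.seed, cfg.genome.chrom_length)
    model = build_model(cfg)
    write_fasta(model.reference, out / "reference.fa")
    write_fasta(model.haplotypes["B"], out / "haplotypeB.fa")
    write_annotation_bed(model.annotation, out / "genes.bed")
    write_truth_json(model, out / "truth.json")

    log.info("stage simulate: depth=%.1f mix=%.2f", cfg.sim.mean_depth, cfg.sim.haplotype_mix)
    sim = SimConfig(**{**asdict(cfg.sim), "seed": read_seed})
    pairs, truth_placement = simulate_reads(model, sim)
    write_fastq_pair(pairs, out / "reads_R1.fastq", out / "reads_R2.fastq")
    truth_placement.to_csv(out / "read_truth.tsv", sep="\t", index=False)

    log.info("stage map: %d pairs", len(pairs))
    index = KmerIndex(model.reference)
    im = cfg.insert_model
    records = map_pairs(pairs, index, im)
    ref_lengths = {c: len(s) for c, s in model.reference.items()}
    samio.write_sam(records, ref_lengths, out / "alignments.sam")

    log.info("stage call: min_support=%d roi=%s", cfg.min_support, cfg.roi)
    records = samio.read_sam(out / "alignments.sam")
    calls = svdiscover.discover(records, im, model.reference, cfg.min_support)
    screened = svdiscover.screen_region(calls, cfg.roi)
    svdiscover.calls_to_frame(screened).to_csv(out / "adjacencies.tsv", sep="\t", index=False)

    log.info("stage copynum")
    counts = cn.count_reads_per_gene(records, model.annotation, list(ref_lengths))
    counts = cn.tpm_normalize(counts)
    counts.genes.to_csv(out / "gene_counts.tsv", sep="\t")
    copies = cn.copy_calls_for_all(counts)
    copies.to_csv(out / "copy_calls.tsv", sep="\t")

    recovered = sum(
        any(match_adjacency(c, t) for c in screened) for t in model.truth_adjacencies
    )
    false_pos = sum(
        not any(match_adjacency(c, t) for t in model.truth_adjacencies) for c in screened
    )
    report = RunReport(
        parameters={
            "seed": cfg.seed,
            "genome": asdict(cfg.genome),
            "sim": asdict(sim),
            "tandem_copies": cfg.tandem_copies,
            "inverted_tail": cfg.inverted_tail,
            "deleted_span": cfg.deleted_span,
            "min_support": cfg.min_support,
            "roi": list(cfg.roi),
        },
        called_adjacencies=[format_adjacency(c) for c in screened],
        truth_adjacencies=[format_adjacency(t) for t in model.truth_adjacencies],
        truth_recovered=recovered,
        false_positives=false_pos,
        copy_estimates={g: round(float(v), 4) for g, v in copies["estimated_copies"].items()},
        truth_copy_number=dict(model.truth_copy_number),
        file_checksums={
            p.name: _md5(p) for p in sorted(out.iterdir()) if p.suffix != ".json" and p.name != "report.txt"
        },
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    (out / "report.txt").write_text(_render_report(report))
    return report


def _render_report(report: RunReport) -> str:
    lines = ["tg-locus run report", "===================", ""]
    lines.append(f"seed: {report.parameters['seed']}")
    lines.append("")
    lines.append("Called adjacencies (after region screen):")
    for a in report.called_adjacencies or ["  (none)"]:
        lines.append(f"  {a}")
    lines.append("Truth adjacencies:")
    for a in report.truth_adjacencies or ["  (none)"]:
        lines.append(f"  {a}")
    lines.append(
        f"Recovered {report.truth_recovered}/{len(report.truth_adjacencies)} truth "
        f"adjacencies; {report.false_positives} false positive(s)."
    )
    lines.append("")
    lines.append("Copy-number estimates (copies per diploid genome):")
    for gid in sorted(report.copy_estimates):
        truth = report.truth_copy_number.get(gid)
        lines.append(f"  {gid:8s} {report.copy_estimates[gid]:6.2f}  (truth {truth})")
    lines.append("")
    return "\n".join(lines) + "\n"
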