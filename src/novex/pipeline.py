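"""Configuration-driven orchestration of the discovery pipeline.

A :class:`PipelineConfig` names the input files (two reference GTFs,
assembled-transcript GTF, junction BED, count and design TSVs, genome
FASTA) and the thresholds; the ``run_*`` functions execute one stage
each and write TSV reports whose columns mirror the published summary
tables.  All stages are deterministic given their inputs, and each one
logs the feature counts at every filter step (the loci -> intergenic ->
enriched funnel) at INFO level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consequence as cq
from .discovery import NovelExonCall, call_novel_transcripts, deduce_novel_exons
from .enrichment import (
    estimate_size_factors,
    exon_usage_test,
    gene_level_test,
    pairwise_enrichment,
)
from .genome_model import (
    AnnotationSet,
    GenomicInterval,
    TranscriptModel,
    read_counts,
    read_design,
    read_fasta,
    read_gtf,
    read_junctions,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "run_discovery",
    "run_enrichment",
    "run_condition_splicing",
    "run_consequence",
    "run_all",
]


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and seed for one pipeline run.

    Thresholds default to the reporting rules used throughout: raw
    p < 0.05 per pairwise comparison, junction support >= 2, >= 5 exons
    for a reportable novel transcript, strictly-upstream uORFs.
    """

    reference_a: Path | None = None
    reference_b: Path | None = None
    assembled: Path | None = None
    junctions: Path | None = None
    counts: Path | None = None
    design: Path | None = None
    genome: Path | None = None
    usage_exon: Path | None = None
    usage_other: Path | None = None
    usage_design: Path | None = None
    outdir: Path = Path("novex_out")
    p_threshold: float = 0.05
    min_support: int = 2
    min_exons: int = 5
    uorf_include_overlapping: bool = False
    seed: int = 20140713

    _PATH_FIELDS = (
        "reference_a",
        "reference_b",
        "assembled",
        "junctions",
        "counts",
        "design",
        "genome",
        "usage_exon",
        "usage_other",
        "usage_design",
    )

    def __post_init__(self) -> None:
        for name in self._PATH_FIELDS:
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))
        self.outdir = Path(self.outdir)
        if not (0 < self.p_threshold < 1):
            raise ConfigError(f"p_threshold must be in (0, 1), got {self.p_threshold}")
        if self.min_support < 0 or self.min_exons < 1:
            raise ConfigError("min_support must be >= 0 and min_exons >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()} - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def require(self, *names: str) -> None:
        """Validate that the named inputs are configured and exist."""
        missing = []
        for name in names:
            v = getattr(self, name)
            if v is None:
                missing.append(f"{name} (not configured)")
            elif not Path(v).exists():
                missing.append(f"{name} ({v} does not exist)")
        if missing:
            raise ConfigError("missing inputs: " + "; ".join(missing))


def _exon_call_row(i: int, call: NovelExonCall) -> dict:
    j1, j2 = call.junction_pair
    return {
        "id": f"NE-{i + 1}",
        "gene": call.host_gene,
        "position": call.exon.position_string(),
        "length": call.exon.length,
        "strand": call.exon.strand,
        "support": call.support,
        "left_junction": f"{j1.donor}-{j1.acceptor}",
        "right_junction": f"{j2.donor}-{j2.acceptor}",
    }


def run_discovery(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call novel transcripts and novel exons; write two TSV reports.

    Returns (novel_transcripts, novel_exons) tables.  An empty junction
    file yields an empty exon table, not an error.
    """
    config.require("reference_a", "reference_b", "assembled", "junctions")
    config.outdir.mkdir(parents=True, exist_ok=True)
    ref_a = read_gtf(config.reference_a, "reference_A")
    ref_b = read_gtf(config.reference_b, "reference_B")
    assembled = read_gtf(config.assembled, "assembled")
    junctions = read_junctions(config.junctions)
    logger.info(
        "discovery inputs: %d assembled transcripts, %d + %d reference transcripts, %d junctions",
        len(assembled), len(ref_a), len(ref_b), len(junctions),
    )

    calls = call_novel_transcripts(list(assembled), [ref_a, ref_b], config.min_exons)
    logger.info("novel transcripts: %d intergenic in both references", len(calls))
    nt = pd.DataFrame(
        [
            {
                "id": c.transcript.id,
                "position": c.locus.position_string(True),
                "n_exons": c.n_exons,
                "class_reference_A": c.class_by_reference["reference_A"].value,
                "class_reference_B": c.class_by_reference["reference_B"].value,
            }
            for c in calls
        ],
        columns=["id", "position", "n_exons", "class_reference_A", "class_reference_B"],
    )

    exon_calls = deduce_novel_exons(junctions, ref_a, config.min_support)
    logger.info("novel exons: %d deduced at support >= %d", len(exon_calls), config.min_support)
    ne = pd.DataFrame(
        [_exon_call_row(i, c) for i, c in enumerate(exon_calls)],
        columns=[
            "id", "gene", "position", "length", "strand",
            "support", "left_junction", "right_junction",
        ],
    )
    nt.to_csv(config.outdir / "novel_transcripts.tsv", sep="\t", index=False)
    ne.to_csv(config.outdir / "novel_exons.tsv", sep="\t", index=False)
    return nt, ne


def run_enrichment(config: PipelineConfig, targets: list[str] | None = None) -> pd.DataFrame:
    """Pairwise tissue enrichment for each target tissue.

    One row per feature per target tissue, with per-comparison p-values,
    ``p-value min`` / ``p-value max`` and the enrichment verdict.
    """
    config.require("counts", "design")
    config.outdir.mkdir(parents=True, exist_ok=True)
    counts = read_counts(config.counts)
    design = read_design(config.design)
    missing = [s for s in counts.columns if s not in design.index]
    if missing:
        raise ConfigError(f"samples missing from design: {missing}")
    if targets is None:
        targets = list(pd.unique(design.loc[counts.columns]))
    size_factors = estimate_size_factors(counts, pseudo_reference=True)
    frames = []
    for target in targets:
        res = pairwise_enrichment(
            counts, design, target, config.p_threshold, size_factors=size_factors
        )
        res = res.reset_index(names="id")
        frames.append(res)
        logger.info("%s: %d features enriched", target, int(res["enriched"].sum()))
    out = pd.concat(frames, ignore_index=True)
    out = out.rename(columns={"p_min": "p-value min", "p_max": "p-value max"})
    out.to_csv(config.outdir / "enrichment.tsv", sep="\t", index=False)
    return out


def run_condition_splicing(config: PipelineConfig) -> pd.DataFrame:
    """Differential exon usage between two conditions (e.g. sham vs TAC).

    Tests each exon's inclusion proportion against the rest of its gene
    and, alongside, the gene-level expression change; rows with
    ``p_usage`` below the threshold are flagged.
    """
    config.require("usage_exon", "usage_other", "usage_design")
    config.outdir.mkdir(parents=True, exist_ok=True)
    exon = read_counts(config.usage_exon)
    other = read_counts(config.usage_other)
    design = read_design(config.usage_design)
    conditions = list(pd.unique(design))
    if len(conditions) != 2:
        raise ConfigError(f"usage design must have exactly 2 conditions, got {conditions}")
    if not exon.index.equals(other.index) or not exon.columns.equals(other.columns):
        raise ConfigError("usage exon/other tables must share features and samples")
    gene_totals = exon + other
    rows = []
    for eid in exon.index:
        res = exon_usage_test(
            exon.loc[eid], other.loc[eid], design.loc[exon.columns], exon_id=eid, gene_id=eid
        )
        p_gene, fold = gene_level_test(gene_totals, design, eid)
        rows.append(
            {
                "exon_id": eid,
                "gene_id": eid,
                "usage_change": res.usage_change,
                "p_usage": res.p_usage,
                "p_gene": p_gene,
                "gene_fold_change": fold,
                "significant": bool(res.p_usage < config.p_threshold)
                if np.isfinite(res.p_usage)
                else False,
            }
        )
    out = pd.DataFrame(rows)
    logger.info(
        "exon usage: %d/%d exons differentially used at p < %g",
        int(out["significant"].sum()), len(out), config.p_threshold,
    )
    out.to_csv(config.outdir / "exon_usage.tsv", sep="\t", index=False)
    return out


def _insert_exon(host: TranscriptModel, exon: GenomicInterval) -> TranscriptModel:
    spans = [(e.interval.start, e.interval.end) for e in host.exons_genomic]
    spans.append((exon.start, exon.end))
    return TranscriptModel.from_intervals(
        host.id + "+novel", host.gene_id, host.chrom, host.strand, spans, "assembled"
    )


def run_consequence(config: PipelineConfig) -> pd.DataFrame:
    """Predict the sequence consequence of each discovered novel exon.

    Re-runs exon deduction, inserts each novel exon into its host
    transcript, and classifies the resulting isoform against the
    reference: UTR class, amino-acid delta, uORF count, and motif
    content (proline-rich windows in any inserted peptide, G-quadruplex
    motifs in the novel 5'UTR).
    """
    config.require("reference_a", "junctions", "genome")
    config.outdir.mkdir(parents=True, exist_ok=True)
    ref_a = read_gtf(config.reference_a, "reference_A")
    junctions = read_junctions(config.junctions)
    genome = read_fasta(config.genome)
    calls = deduce_novel_exons(junctions, ref_a, config.min_support)
    by_tid = {t.id: t for t in ref_a.transcripts}
    rows = []
    for i, call in enumerate(calls):
        host = by_tid[call.host_transcript]
        novel_t = _insert_exon(host, call.exon)
        cc = cq.classify_consequence(
            host, novel_t, genome,
            uorf_include_overlapping=config.uorf_include_overlapping,
        )
        nov_s = cq.splice_sequence(novel_t, genome)
        orf = cq.find_main_orf(nov_s)
        utr5 = nov_s.sequence[: orf.start] if orf is not None else ""
        g4 = cq.scan_g_quadruplex(utr5)
        rows.append(
            {
                "id": f"NE-{i + 1}",
                "gene": call.host_gene,
                "position": call.exon.position_string(),
                "length": call.exon.length,
                "prediction": cc.category.value,
                "aa_delta": cc.aa_delta if cc.aa_delta is not None else "",
                "uorf_count": cc.uorf_count,
                "utr5_g_quadruplexes": len(g4),
                "notes": cc.notes,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "id", "gene", "position", "length", "prediction",
            "aa_delta", "uorf_count", "utr5_g_quadruplexes", "notes",
        ],
    )
    logger.info("consequence: %d novel exons classified", len(out))
    out.to_csv(config.outdir / "consequence.tsv", sep="\t", index=False)
    return out


def run_all(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run discovery, enrichment, exon usage and consequence in order."""
    results: dict[str, pd.DataFrame] = {}
    nt, ne = run_discovery(config)
    results["novel_transcripts"], results["novel_exons"] = nt, ne
    if config.counts is not None:
        results["enrichment"] = run_enrichment(config)
    if config.usage_exon is not None:
        results["exon_usage"] = run_condition_splicing(config)
    if config.genome is not None:
        results["consequence"] = run_consequence(config)
    return results
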