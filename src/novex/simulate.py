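"""Ground-truthed synthetic inputs for the discovery/enrichment pipeline.

The generator emulates the structure of a six-tissue bulk RNA-seq
discovery study plus a two-condition (sham vs TAC pressure-overload)
cardiac design:

* a random genome split into contigs;
* two reference annotations of the same gene set that disagree on a
  configurable fraction of gene models (each divergent gene is kept in
  only one reference), exercising the "unknown in both references"
  conjunction;
* an assembled transcript set = all reference transcripts plus planted
  intergenic multi-exon transcripts (5-22 exons, the exon-count range
  observed for published novel transcripts);
* a junction file containing all annotated junctions plus the planted
  novel junction pairs that define cassette exons inside known introns;
* a negative-binomial count matrix over 6 tissues x n replicates with
  planted tissue-enriched features (default 100-fold, within the
  published 8.3-1,328-fold enrichment range);
* exon/rest-of-gene count tables for a sham/TAC design with n = 3 per
  group and a planted inclusion shift.

Every generator is a pure function of its parameters and seed, and the
planted truth serializes losslessly to JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import (
    AnnotationSet,
    GenomicInterval,
    SpliceJunction,
    TranscriptModel,
    merge_junctions,
    write_counts,
    write_design,
    write_fasta,
    write_gtf,
    write_junctions,
)

__all__ = [
    "SyntheticTruth",
    "generate_genome",
    "generate_annotation_pair",
    "plant_novelty",
    "simulate_counts",
    "simulate_condition_usage",
    "generate_bundle",
    "TISSUES",
]

TISSUES = ("brain", "cerebrum", "heart", "kidney", "liver", "testes")
DEFAULT_SEED = 20140713


@dataclass
class PlantedExon:
    exon_id: str
    host_gene: str
    host_transcript: str
    exon: tuple[str, int, int, str]  # chrom, start, end, strand (1-based inclusive)
    junctions: tuple[tuple[int, int], tuple[int, int]]  # (donor, acceptor) pairs
    support: int


@dataclass
class SyntheticTruth:
    """Everything planted into a synthetic bundle."""

    seed: int
    planted_transcript_ids: list[str] = field(default_factory=list)
    planted_transcript_loci: dict[str, str] = field(default_factory=dict)
    planted_exons: list[PlantedExon] = field(default_factory=list)
    enrichment: dict[str, tuple[str, float]] = field(default_factory=dict)  # feature -> (tissue, fold)
    nb_parameters: dict[str, tuple[float, float]] = field(default_factory=dict)  # feature -> (mean, alpha)
    size_factors: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        exons = [
            PlantedExon(
                e["exon_id"],
                e["host_gene"],
                e["host_transcript"],
                tuple(e["exon"]),
                (tuple(e["junctions"][0]), tuple(e["junctions"][1])),
                e["support"],
            )
            for e in raw.pop("planted_exons")
        ]
        truth = cls(seed=raw["seed"])
        truth.planted_transcript_ids = raw["planted_transcript_ids"]
        truth.planted_transcript_loci = raw["planted_transcript_loci"]
        truth.planted_exons = exons
        truth.enrichment = {k: (v[0], float(v[1])) for k, v in raw["enrichment"].items()}
        truth.nb_parameters = {k: (float(v[0]), float(v[1])) for k, v in raw["nb_parameters"].items()}
        truth.size_factors = {k: float(v) for k, v in raw["size_factors"].items()}
        return truth


def generate_genome(
    n_contigs: int = 4,
    contig_length: int = 600_000,
    seed: int = DEFAULT_SEED,
) -> dict[str, str]:
    """Uniform random nucleotide contigs, reproducible by seed."""
    if contig_length < 10_000:
        raise ValueError("contig_length must be >= 10 kb")
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    return {
        f"chr{i + 1}": b"".join(rng.choice(alphabet, size=contig_length)).decode()
        for i in range(n_contigs)
    }


def _random_gene(
    rng: np.random.Generator,
    start: int,
    n_exons: int,
    exon_len: tuple[int, int] = (80, 300),
    intron_len: tuple[int, int] = (300, 1500),
) -> list[tuple[int, int]]:
    spans = []
    pos = start
    for i in range(n_exons):
        L = int(rng.integers(exon_len[0], exon_len[1] + 1))
        spans.append((pos, pos + L - 1))
        if i < n_exons - 1:
            pos += L + int(rng.integers(intron_len[0], intron_len[1] + 1))
        else:
            pos += L
    return spans


def generate_annotation_pair(
    genome: dict[str, str],
    n_genes: int = 100,
    divergence: float = 0.2,
    seed: int = DEFAULT_SEED,
) -> tuple[AnnotationSet, AnnotationSet, dict]:
    """Two references over one simulated gene set.

    Genes are packed left to right along the contigs with intergenic
    gaps of 3-15 kb.  Each gene independently diverges with probability
    ``divergence``; a divergent gene is dropped from one of the two
    references (alternating), so it is annotated in exactly one source.
    Returns (reference_A, reference_B, layout) where layout records
    gene placements and the free intergenic gaps available for planting.
    """
    rng = np.random.default_rng(seed)
    contigs = list(genome)
    genes: list[TranscriptModel] = []
    gaps: list[tuple[str, int, int]] = []  # chrom, free start, free end (1-based)
    per_contig = [n_genes // len(contigs)] * len(contigs)
    for i in range(n_genes % len(contigs)):
        per_contig[i] += 1
    gi = 0
    for chrom, n_here in zip(contigs, per_contig):
        contig_len = len(genome[chrom])
        pos = 1
        for _ in range(n_here):
            gap = int(rng.integers(3000, 9001))
            n_exons = int(rng.integers(3, 11))
            spans = _random_gene(rng, pos + gap, n_exons)
            strand = "+" if rng.random() < 0.5 else "-"
            end = spans[-1][1]
            if end > contig_len - 1000:
                raise ValueError(
                    f"gene packing infeasible: contig {chrom} too short for requested gene count"
                )
            gi += 1
            gid = f"gene{gi:04d}"
            genes.append(TranscriptModel.from_intervals(f"{gid}.t1", gid, chrom, strand, spans, "reference"))
            gaps.append((chrom, pos + 500, pos + gap - 500))
            pos = end
        gaps.append((chrom, pos + 500, contig_len - 500))

    diverge = rng.random(len(genes)) < divergence
    side = 0
    only_a, only_b = set(), set()
    for t, d in zip(genes, diverge):
        if d:
            (only_a if side == 0 else only_b).add(t.gene_id)
            side = 1 - side
    ref_a = AnnotationSet(
        [t for t in genes if t.gene_id not in only_b], label="reference_A"
    )
    ref_b = AnnotationSet(
        [t for t in genes if t.gene_id not in only_a], label="reference_B"
    )
    layout = {
        "genes": genes,
        "gaps": [g for g in gaps if g[2] - g[1] > 2000],
        "only_a": only_a,
        "only_b": only_b,
        "shared": {t.gene_id for t in genes} - only_a - only_b,
    }
    return ref_a, ref_b, layout


def plant_novelty(
    ref_a: AnnotationSet,
    ref_b: AnnotationSet,
    layout: dict,
    n_novel_transcripts: int = 10,
    n_novel_exons: int = 10,
    seed: int = DEFAULT_SEED,
    junction_support: tuple[int, int] = (5, 50),
) -> tuple[list[TranscriptModel], list[SpliceJunction], SyntheticTruth]:
    """Plant intergenic transcripts and intronic cassette exons.

    Returns (assembled transcripts, junctions, truth).  The assembled
    set is every reference_A transcript plus the planted intergenic
    transcripts (5-22 exons each, placed in gaps free in both
    references).  The junction list holds all annotated junctions of
    reference_A plus the planted novel junction pairs, each planted
    junction supported by 5-50 reads.  At most one exon is planted per
    intron, and only in genes shared by both references, so planted
    calls are unambiguous.
    """
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)

    # --- intergenic transcripts ---
    gaps = sorted(layout["gaps"], key=lambda g: g[2] - g[1], reverse=True)
    planted_transcripts: list[TranscriptModel] = []
    if n_novel_transcripts > len(gaps):
        raise ValueError("not enough intergenic space for requested novel transcripts")
    for i in range(n_novel_transcripts):
        chrom, lo, hi = gaps[i]
        tid = f"novelT{i + 1:03d}"
        for _attempt in range(50):
            n_exons = int(rng.integers(5, 23))
            avail = hi - lo
            # budget exon/intron sizes to the gap
            max_intron = max(60, min(500, (avail - n_exons * 200) // max(n_exons - 1, 1)))
            spans = _random_gene(
                rng, lo + int(rng.integers(0, 200)),
                n_exons, exon_len=(80, 200), intron_len=(60, max_intron),
            )
            if spans[-1][1] <= hi:
                break
        else:
            raise ValueError(f"could not fit a planted transcript into gap {gaps[i]}")
        strand = "+" if rng.random() < 0.5 else "-"
        t = TranscriptModel.from_intervals(tid, tid, chrom, strand, spans, "assembled")
        planted_transcripts.append(t)
        truth.planted_transcript_ids.append(tid)
        truth.planted_transcript_loci[tid] = t.span.position_string(True)

    # --- intronic cassette exons ---
    shared = layout["shared"]
    candidates = []
    for t in ref_a.transcripts:
        if t.gene_id not in shared:
            continue
        g = t.exons_genomic
        for a, b in zip(g, g[1:]):
            intron_len = b.interval.start - a.interval.end - 1
            if intron_len >= 400:
                candidates.append((t, a, b))
    if n_novel_exons > len(candidates):
        raise ValueError("not enough long introns for requested novel exons")
    order = rng.permutation(len(candidates))
    used_introns: set[tuple] = set()
    planted_junctions: list[SpliceJunction] = []
    n_done = 0
    for idx in order:
        if n_done == n_novel_exons:
            break
        t, a, b = candidates[idx]
        intron_key = (t.chrom, a.interval.end, b.interval.start)
        if intron_key in used_introns:
            continue
        used_introns.add(intron_key)
        intron_lo, intron_hi = a.interval.end + 1, b.interval.start - 1
        exon_len = int(rng.integers(80, 201))
        flank = 50
        max_start = intron_hi - exon_len + 1 - flank
        min_start = intron_lo + flank
        if max_start <= min_start:
            continue
        ex_start = int(rng.integers(min_start, max_start + 1))
        ex_end = ex_start + exon_len - 1
        support = int(rng.integers(junction_support[0], junction_support[1] + 1))
        j1 = SpliceJunction(t.chrom, a.interval.end, ex_start, t.strand, support)
        j2 = SpliceJunction(t.chrom, ex_end, b.interval.start, t.strand, support)
        n_done += 1
        exon_id = f"novelE{n_done:03d}"
        truth.planted_exons.append(
            PlantedExon(
                exon_id,
                t.gene_id,
                t.id,
                (t.chrom, ex_start, ex_end, t.strand),
                ((j1.donor, j1.acceptor), (j2.donor, j2.acceptor)),
                support,
            )
        )
        planted_junctions.extend([j1, j2])
    if n_done < n_novel_exons:
        raise ValueError("could not place all requested novel exons")

    annotated = [
        SpliceJunction(j.chrom, j.donor, j.acceptor, j.strand, int(rng.integers(10, 101)))
        for j in ref_a.junction_set.values()
    ]
    novel_transcript_junctions = [
        SpliceJunction(j.chrom, j.donor, j.acceptor, j.strand, int(rng.integers(*junction_support)))
        for t in planted_transcripts
        for j in t.junctions()
    ]
    junctions = merge_junctions(annotated + planted_junctions + novel_transcript_junctions)
    assembled = list(ref_a.transcripts) + planted_transcripts
    return assembled, junctions, truth


def simulate_counts(
    truth: SyntheticTruth,
    background_features: list[str],
    tissues: tuple[str, ...] = TISSUES,
    n_replicates: int = 2,
    fold: float = 100.0,
    baseline_log_mean: float = 4.0,
    baseline_log_sd: float = 1.0,
    dispersion_range: tuple[float, float] = (0.05, 0.5),
    seed: int = DEFAULT_SEED,
) -> tuple[pd.DataFrame, pd.Series]:
    """NB count matrix over tissues x replicates with planted enrichment.

    Planted novel transcripts are enriched ``fold``-fold in testes
    (80%) or liver (20%); planted novel exons in testes or heart
    (alternating).  Baseline per-feature means are log-normal
    (exp(N(4, 1))), dispersions log-uniform in ``dispersion_range``,
    and per-sample size factors log-uniform in [0.5, 2].  The truth
    object is updated in place with the planted parameters.
    """
    rng = np.random.default_rng(seed)
    tids = truth.planted_transcript_ids
    eids = [e.exon_id for e in truth.planted_exons]
    for i, fid in enumerate(tids):
        truth.enrichment[fid] = ("testes" if i < int(np.ceil(0.8 * len(tids))) else "liver", fold)
    for i, fid in enumerate(eids):
        truth.enrichment[fid] = ("testes" if i % 2 == 0 else "heart", fold)

    features = list(background_features) + tids + eids
    samples = [f"{t}_{r + 1}" for t in tissues for r in range(n_replicates)]
    design = pd.Series([t for t in tissues for _ in range(n_replicates)], index=samples, name="group")
    s = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(samples)))
    size_factors = pd.Series(s, index=samples)
    truth.size_factors = {k: float(v) for k, v in size_factors.items()}

    mu_base = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, size=len(features)))
    lo, hi = dispersion_range
    alpha = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(features)))
    counts = np.zeros((len(features), len(samples)), dtype=int)
    for i, fid in enumerate(features):
        truth.nb_parameters[fid] = (float(mu_base[i]), float(alpha[i]))
        target, f = truth.enrichment.get(fid, (None, 1.0))
        mu = np.array(
            [mu_base[i] * (f if design[sm] == target else 1.0) * size_factors[sm] for sm in samples]
        )
        r = 1.0 / alpha[i]
        counts[i] = rng.negative_binomial(r, r / (r + mu))
    return pd.DataFrame(counts, index=features, columns=samples), design


def simulate_condition_usage(
    exon_ids: list[str],
    inclusion_baseline: float = 0.33,
    inclusion_alt: float = 0.12,
    depth: float = 2000.0,
    n_per_group: int = 3,
    gene_fold: float = 1.0,
    gene_dispersion: float = 0.1,
    conditions: tuple[str, str] = ("sham", "TAC"),
    seed: int = DEFAULT_SEED,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Two-condition exon/rest-of-gene tables with a planted usage shift.

    Per sample, the gene total is NB(depth x fold, alpha) and the exon
    count binomial in the gene total with the condition's inclusion
    fraction.  Returns (exon_counts, other_counts, design); "other" is
    the rest of the gene (total minus exon).
    """
    for incl in (inclusion_baseline, inclusion_alt):
        if not 0.0 < incl < 1.0:
            raise ValueError("inclusion fractions must be in (0, 1)")
    rng = np.random.default_rng(seed)
    samples = [f"{c}_{r + 1}" for c in conditions for r in range(n_per_group)]
    design = pd.Series(
        [c for c in conditions for _ in range(n_per_group)], index=samples, name="group"
    )
    r = 1.0 / gene_dispersion
    exon_rows, other_rows = [], []
    for _eid in exon_ids:
        exon_row, other_row = [], []
        for sm in samples:
            alt = design[sm] == conditions[1]
            mu = depth * (gene_fold if alt else 1.0)
            total = int(rng.negative_binomial(r, r / (r + mu)))
            incl = inclusion_alt if alt else inclusion_baseline
            e = int(rng.binomial(total, incl)) if total > 0 else 0
            exon_row.append(e)
            other_row.append(total - e)
        exon_rows.append(exon_row)
        other_rows.append(other_row)
    exon_df = pd.DataFrame(exon_rows, index=exon_ids, columns=samples)
    other_df = pd.DataFrame(other_rows, index=exon_ids, columns=samples)
    return exon_df, other_df, design


def generate_bundle(
    outdir,
    seed: int = DEFAULT_SEED,
    n_genes: int = 100,
    n_novel_transcripts: int = 10,
    n_novel_exons: int = 10,
    n_contigs: int = 4,
    contig_length: int = 600_000,
    divergence: float = 0.2,
    fold: float = 100.0,
    n_replicates: int = 2,
    usage_inclusion: tuple[float, float] = (0.33, 0.12),
    usage_depth: float = 2000.0,
    usage_n_per_group: int = 3,
) -> SyntheticTruth:
    """Emit a complete synthetic input bundle under ``outdir``.

    Files: genome.fa, reference_A.gtf (quoted attributes),
    reference_B.gtf (unquoted attributes), assembled.gtf,
    junctions.bed, counts.tsv, design.tsv, usage_exon.tsv,
    usage_other.tsv, usage_design.tsv and truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = [int(x) for x in rng.integers(0, 2**31 - 1, size=5)]
    genome = generate_genome(n_contigs, contig_length, seed=sub[0])
    ref_a, ref_b, layout = generate_annotation_pair(genome, n_genes, divergence, seed=sub[1])
    assembled, junctions, truth = plant_novelty(
        ref_a, ref_b, layout, n_novel_transcripts, n_novel_exons, seed=sub[2]
    )
    counts, design = simulate_counts(
        truth,
        background_features=[t.gene_id for t in layout["genes"]],
        fold=fold,
        n_replicates=n_replicates,
        seed=sub[3],
    )
    exon_df, other_df, usage_design = simulate_condition_usage(
        [e.exon_id for e in truth.planted_exons],
        inclusion_baseline=usage_inclusion[0],
        inclusion_alt=usage_inclusion[1],
        depth=usage_depth,
        n_per_group=usage_n_per_group,
        seed=sub[4],
    )
    write_fasta(genome, outdir / "genome.fa")
    write_gtf(ref_a, outdir / "reference_A.gtf", source="reference_A", quoted=True)
    write_gtf(ref_b, outdir / "reference_B.gtf", source="reference_B", quoted=False)
    write_gtf(assembled, outdir / "assembled.gtf", source="assembled", quoted=True)
    write_junctions(junctions, outdir / "junctions.bed")
    write_counts(counts, outdir / "counts.tsv")
    write_design(design, outdir / "design.tsv")
    write_counts(exon_df, outdir / "usage_exon.tsv")
    write_counts(other_df, outdir / "usage_other.tsv")
    write_design(usage_design, outdir / "usage_design.tsv")
    truth.to_json(outdir / "truth.json")
    return truth
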