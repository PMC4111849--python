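"""Novel transcript and novel exon discovery.

Two discovery procedures operate on assembled transcript models and
observed splice junctions:

* **Intergenic novel transcripts** — an assembled transcript is
  classified against each reference annotation (KNOWN > EXONIC_OVERLAP >
  INTRONIC > INTERGENIC, in that precedence) and reported as a putative
  novel transcript only when it is INTERGENIC in *every* reference
  supplied, i.e. unknown to all of them, and carries at least
  ``min_exons`` exons.

* **Novel cassette exons** — for each annotated intron, a pair of
  unannotated ("novel") junctions whose outer boundaries coincide with
  the flanking known exons defines a novel internal exon spanning the
  region between the two junctions.  Both junctions must be absent from
  the annotated junction set and supported by at least ``min_support``
  spliced reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_model import (
    AnnotationSet,
    ExonRecord,
    GenomicInterval,
    SpliceJunction,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptClass",
    "NovelTranscriptCall",
    "NovelExonCall",
    "classify_transcript",
    "call_novel_transcripts",
    "deduce_novel_exons",
    "exon_inclusion_fraction",
]


class TranscriptClass(Enum):
    """Mutually exclusive transcript classes, in precedence order."""

    KNOWN = "known"
    EXONIC_OVERLAP = "exonic_overlap"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"


@dataclass(frozen=True)
class NovelTranscriptCall:
    transcript: TranscriptModel
    locus: GenomicInterval
    class_by_reference: Mapping[str, TranscriptClass]
    n_exons: int


@dataclass(frozen=True)
class NovelExonCall:
    """A deduced cassette exon strictly inside a known intron."""

    exon: GenomicInterval
    host_gene: str
    host_transcript: str
    flanking_exons: tuple[ExonRecord, ExonRecord]
    junction_pair: tuple[SpliceJunction, SpliceJunction]
    support: int

    def __post_init__(self) -> None:
        left, right = self.junction_pair
        if self.exon.start != left.acceptor or self.exon.end != right.donor:
            raise ValueError("exon boundaries must equal (left acceptor, right donor)")
        a, b = self.flanking_exons
        if not (a.interval.end < self.exon.start and self.exon.end < b.interval.start):
            raise ValueError("novel exon must lie strictly inside the flanking intron")


def classify_transcript(t: TranscriptModel, ann: AnnotationSet) -> TranscriptClass:
    """Classify one assembled transcript against one reference.

    KNOWN requires an identical intron chain (or, for single-exon
    models, an exactly matching annotated single-exon transcript);
    EXONIC_OVERLAP any exon/exon overlap regardless of strand; INTRONIC
    a span contained in an annotated gene span without exon overlap;
    INTERGENIC everything else.  An unknown chromosome is INTERGENIC by
    definition (and logged).
    """
    if t.chrom not in ann.exon_index and t.chrom not in ann.gene_index:
        logger.info("chromosome %s absent from %s; %s classified intergenic", t.chrom, ann.label, t.id)
        return TranscriptClass.INTERGENIC
    if ann.has_intron_chain(t):
        return TranscriptClass.KNOWN
    if any(ann.overlapping_exons(e.interval) for e in t.exons):
        return TranscriptClass.EXONIC_OVERLAP
    if ann.genes_containing(t.span):
        return TranscriptClass.INTRONIC
    return TranscriptClass.INTERGENIC


def call_novel_transcripts(
    assembled: Iterable[TranscriptModel],
    refs: Sequence[AnnotationSet],
    min_exons: int = 5,
) -> list[NovelTranscriptCall]:
    """Transcripts INTERGENIC in every reference, with >= min_exons exons.

    The conjunction over references mirrors requiring a transcript to be
    unknown in two independent annotation sources before reporting it.
    """
    if not refs:
        raise ValueError("at least one reference annotation is required")
    calls = []
    for t in assembled:
        classes = {ref.label: classify_transcript(t, ref) for ref in refs}
        if all(c is TranscriptClass.INTERGENIC for c in classes.values()) and t.n_exons >= min_exons:
            calls.append(NovelTranscriptCall(t, t.span, classes, t.n_exons))
    return calls


def deduce_novel_exons(
    junctions: Iterable[SpliceJunction],
    ann: AnnotationSet,
    min_support: int = 2,
) -> list[NovelExonCall]:
    """Deduce cassette exons from consecutive novel junctions.

    For every annotated intron between known neighbouring exons A and B,
    every pair of unannotated junctions (J1, J2) with J1 anchored at the
    end of A, J2 anchored at the start of B, J1.acceptor <= J2.donor and
    both supported by >= min_support reads yields the exon
    ``[J1.acceptor, J2.donor]``.  Calls are deduplicated by exact exon
    coordinates (the best-supported pair is kept).
    """
    novel = [
        j
        for j in junctions
        if j.read_support >= min_support and not ann.junction_annotated(j)
    ]
    # index novel junctions by anchored boundary
    by_donor: dict[tuple[str, int], list[SpliceJunction]] = {}
    by_acceptor: dict[tuple[str, int], list[SpliceJunction]] = {}
    for j in novel:
        by_donor.setdefault((j.chrom, j.donor), []).append(j)
        by_acceptor.setdefault((j.chrom, j.acceptor), []).append(j)

    def strand_ok(j: SpliceJunction, strand: str) -> bool:
        return j.strand == "." or strand == "." or j.strand == strand

    best: dict[tuple, NovelExonCall] = {}
    seen_introns: set[tuple] = set()
    for t in ann.transcripts:
        g = t.exons_genomic
        for a, b in zip(g, g[1:]):
            intron_key = (t.chrom, t.strand, a.interval.end, b.interval.start)
            if intron_key in seen_introns:
                continue
            seen_introns.add(intron_key)
            lefts = [
                j
                for j in by_donor.get((t.chrom, a.interval.end), [])
                if strand_ok(j, t.strand) and j.acceptor < b.interval.start
            ]
            rights = [
                j
                for j in by_acceptor.get((t.chrom, b.interval.start), [])
                if strand_ok(j, t.strand) and j.donor > a.interval.end
            ]
            for j1 in lefts:
                for j2 in rights:
                    if j2.donor < j1.acceptor:
                        continue  # pathological pair; no exon in between
                    exon = GenomicInterval(t.chrom, j1.acceptor, j2.donor, t.strand)
                    call = NovelExonCall(
                        exon=exon,
                        host_gene=t.gene_id,
                        host_transcript=t.id,
                        flanking_exons=(a, b),
                        junction_pair=(j1, j2),
                        support=min(j1.read_support, j2.read_support),
                    )
                    key = (exon.chrom, exon.start, exon.end)
                    prev = best.get(key)
                    if prev is None or call.support > prev.support:
                        best[key] = call
    return sorted(best.values(), key=lambda c: (c.exon.chrom, c.exon.start, c.exon.end))


def exon_inclusion_fraction(novel_counts, gene_counts) -> np.ndarray:
    """Per-sample fraction of gene expression carried by the novel exon.

    Returns ``novel / gene`` elementwise; 0/0 is undefined and reported
    as NaN.  Novel counts exceeding gene counts indicate inconsistent
    counting and raise ``ValueError``.
    """
    novel = np.asarray(novel_counts, dtype=float)
    gene = np.asarray(gene_counts, dtype=float)
    if novel.shape != gene.shape:
        raise ValueError("novel and gene count vectors must align")
    if (novel < 0).any() or (gene < 0).any():
        raise ValueError("counts must be nonnegative")
    if (novel > gene).any():
        raise ValueError("novel exon counts exceed gene counts (inconsistent counting)")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(gene > 0, novel / np.where(gene > 0, gene, 1.0), np.nan)
    return frac
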