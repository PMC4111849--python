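"""Sequence-level consequences of novel-exon inclusion.

Given a reference isoform and a novel isoform that differs by the
insertion of one or more exons, this module predicts what the inclusion
does to the mature transcript: an alternative 5' or 3' UTR leaving the
protein untouched, an N-terminal change, a C-terminal truncation, an
in-frame internal insertion, or a frame disruption.  It also counts
upstream open reading frames (uORFs) in the novel 5'UTR and scans for
two regulatory motifs repeatedly associated with such exons:
proline-rich windows in the encoded peptide and G-quadruplex-forming
runs in the nucleotide sequence.

The main-ORF rule is deterministic — the longest ATG-initiated open
reading frame with an in-frame stop, ties broken 5'-most — standing in
for the manual ORF selection a curator would perform.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from Bio.Seq import Seq

from .genome_model import GenomicInterval, TranscriptModel, fetch_sequence

__all__ = [
    "SplicedSequence",
    "OrfCall",
    "ConsequenceCategory",
    "ConsequenceCall",
    "splice_sequence",
    "find_main_orf",
    "count_uorfs",
    "classify_consequence",
    "scan_proline_rich",
    "scan_g_quadruplex",
]

_STOPS = {"TAA", "TAG", "TGA"}
DEFAULT_MAIN_ORF_MIN_CODONS = 30
DEFAULT_UORF_MIN_CODONS = 3  # ATG + >= 1 codon + stop


@dataclass(frozen=True)
class SplicedSequence:
    """A mature (spliced) transcript sequence, 5'->3'.

    ``exon_offsets`` gives each exon's [start, end) offsets within the
    spliced sequence, in transcript (rank) order.
    """

    transcript_id: str
    sequence: str
    exon_offsets: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        total = sum(e - s for s, e in self.exon_offsets)
        if total != len(self.sequence):
            raise ValueError("sequence length must equal the sum of exon lengths")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("sequence alphabet must be within {A,C,G,T,N}")


@dataclass(frozen=True)
class OrfCall:
    """An ATG-initiated reading frame within a spliced sequence.

    Offsets are 0-based within the spliced sequence; ``end`` is
    exclusive and includes the stop codon when one exists.  The peptide
    excludes the stop.  ``has_stop`` is False for an ORF running off the
    3' end of the sequence.
    """

    start: int
    end: int
    peptide: str
    has_stop: bool = True

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")


class ConsequenceCategory(Enum):
    ALT_5UTR = "alternative_5utr"
    ALT_3UTR = "alternative_3utr"
    NTERM_CHANGE = "n_terminal_change"
    CTERM_TRUNCATION = "c_terminal_truncation"
    INTERNAL_INSERTION = "internal_insertion"
    FRAME_DISRUPTION = "frame_disruption"
    NONCODING = "noncoding"


@dataclass(frozen=True)
class ConsequenceCall:
    category: ConsequenceCategory
    aa_delta: Optional[int]  # novel peptide length - reference peptide length
    uorf_count: int
    notes: str = ""


def splice_sequence(t: TranscriptModel, genome) -> SplicedSequence:
    """Concatenate exon sequences in transcript order.

    Minus-strand transcripts are reverse-complemented.  ``genome`` may
    be any mapping from contig name to a sliceable sequence (a plain
    dict of strings or a ``pyfaidx.Fasta``).
    """
    parts = []
    lengths = []
    for e in t.exons_genomic:
        iv = e.interval
        contig = genome[iv.chrom]
        contig_len = len(contig)
        if iv.end0 > contig_len:
            raise ValueError(
                f"exon {iv.position_string()} extends beyond contig end ({contig_len})"
            )
        parts.append(fetch_sequence(genome, iv.chrom, iv.start0, iv.end0))
        lengths.append(iv.length)
    seq = "".join(parts)
    if t.strand == "-":
        seq = str(Seq(seq).reverse_complement())
        lengths = lengths[::-1]
    offsets = []
    pos = 0
    for L in lengths:
        offsets.append((pos, pos + L))
        pos += L
    return SplicedSequence(t.id, seq, tuple(offsets))


def _orf_from(seq: str, start: int) -> tuple[int, bool]:
    """End offset (exclusive, stop included) and stop flag for the frame at start."""
    for i in range(start + 3, len(seq) - 2, 3):
        if seq[i : i + 3] in _STOPS:
            return i + 3, True
    # run off the end: truncate to a codon multiple
    n = (len(seq) - start) // 3
    return start + 3 * n, False


def _translate(seq: str) -> str:
    """Standard-code translation; N-containing codons become X."""
    pep = str(Seq(seq).translate())
    return pep.replace("*", "")  # callers pass stop-free or single trailing stop


def find_main_orf(s: SplicedSequence, min_codons: int = DEFAULT_MAIN_ORF_MIN_CODONS) -> Optional[OrfCall]:
    """The longest ATG-initiated ORF with an in-frame stop, ties 5'-most.

    If no stopped ORF reaches ``min_codons`` (codons counted without
    the stop), the longest stop-less ORF is used if it qualifies,
    flagged via ``has_stop=False``.  Returns None (a noncoding signal)
    when nothing qualifies.
    """
    seq = s.sequence
    best: Optional[OrfCall] = None
    best_open: Optional[OrfCall] = None
    for m in re.finditer("ATG", seq):
        start = m.start()
        end, has_stop = _orf_from(seq, start)
        codons = (end - start) // 3 - (1 if has_stop else 0)
        if codons < min_codons:
            continue
        coding = seq[start : end - 3] if has_stop else seq[start:end]
        call = OrfCall(start, end, _translate(coding), has_stop)
        if has_stop:
            if best is None or len(call.peptide) > len(best.peptide):
                best = call
        else:
            if best_open is None or len(call.peptide) > len(best_open.peptide):
                best_open = call
    return best if best is not None else best_open


def count_uorfs(
    s: SplicedSequence,
    main_start: int,
    min_codons: int = DEFAULT_UORF_MIN_CODONS,
    include_overlapping: bool = False,
) -> int:
    """Number of distinct upstream ATGs opening a uORF in the 5'UTR.

    By default a uORF must be *fully* upstream: its in-frame stop codon
    ends at or before ``main_start``, and its total length (start
    through stop) spans at least ``min_codons`` codons.  With
    ``include_overlapping=True``, upstream ATGs whose frame runs past
    the main start (or never stops) are counted as well.  The main
    start itself is never counted, and nothing downstream of it ever
    contributes.
    """
    seq = s.sequence
    count = 0
    for m in re.finditer("ATG", seq[: max(main_start, 0)]):
        start = m.start()
        end, has_stop = _orf_from(seq, start)
        if has_stop and end <= main_start:
            if (end - start) // 3 >= min_codons:
                count += 1
        elif include_overlapping:
            count += 1
    return count


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _common_suffix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


def _inserted_regions(ref_t: TranscriptModel, novel_t: TranscriptModel) -> list[tuple[int, int]]:
    """Spliced-sequence offsets (in the novel isoform) of inserted exons."""
    ref_exons = {(e.interval.start, e.interval.end) for e in ref_t.exons}
    regions = []
    pos = 0
    for e in novel_t.exons:  # transcript order matches spliced offsets
        L = e.interval.length
        if (e.interval.start, e.interval.end) not in ref_exons:
            regions.append((pos, pos + L))
        pos += L
    return regions


def classify_consequence(
    ref_t: TranscriptModel,
    novel_t: TranscriptModel,
    genome,
    min_codons: int = DEFAULT_MAIN_ORF_MIN_CODONS,
    uorf_min_codons: int = DEFAULT_UORF_MIN_CODONS,
    uorf_include_overlapping: bool = False,
) -> ConsequenceCall:
    """Predict the consequence of including the novel exon(s).

    The two isoforms are spliced and translated under the main-ORF rule
    and their peptides compared:

    * identical peptides -> ALT_5UTR or ALT_3UTR, decided by where the
      inserted exons fall relative to the novel ORF;
    * one peptide a suffix of the other -> NTERM_CHANGE;
    * one peptide a prefix of the other -> CTERM_TRUNCATION when the
      novel one is shorter, otherwise a C-terminal extension reported as
      INTERNAL_INSERTION (boundary case, noted);
    * shared prefix + suffix covering the whole reference with extra
      interior residues -> INTERNAL_INSERTION;
    * shared prefix, no shared suffix, shorter novel peptide (a
      premature in-frame stop) -> CTERM_TRUNCATION;
    * anything else -> FRAME_DISRUPTION.

    Either isoform lacking a qualifying ORF yields NONCODING with an
    undefined aa_delta.  ``uorf_count`` is always computed on the novel
    isoform's 5'UTR (0 when the novel isoform is noncoding).
    """
    ref_s = splice_sequence(ref_t, genome)
    nov_s = splice_sequence(novel_t, genome)
    ref_orf = find_main_orf(ref_s, min_codons)
    nov_orf = find_main_orf(nov_s, min_codons)
    uorfs = (
        count_uorfs(nov_s, nov_orf.start, uorf_min_codons, uorf_include_overlapping)
        if nov_orf is not None
        else 0
    )
    if ref_orf is None or nov_orf is None:
        return ConsequenceCall(ConsequenceCategory.NONCODING, None, uorfs, "no qualifying ORF")

    pep_r, pep_n = ref_orf.peptide, nov_orf.peptide
    delta = len(pep_n) - len(pep_r)
    if pep_n == pep_r:
        regions = _inserted_regions(ref_t, novel_t)
        if regions and all(e <= nov_orf.start for _s, e in regions):
            return ConsequenceCall(ConsequenceCategory.ALT_5UTR, 0, uorfs)
        if regions and all(s >= nov_orf.end for s, _e in regions):
            return ConsequenceCall(ConsequenceCategory.ALT_3UTR, 0, uorfs)
        return ConsequenceCall(
            ConsequenceCategory.ALT_5UTR, 0, uorfs, "insertion overlaps ORF but peptide unchanged"
        )

    p = _common_prefix(pep_r, pep_n)
    s = _common_suffix(pep_r, pep_n)
    shorter = min(len(pep_r), len(pep_n))
    if s >= shorter:
        return ConsequenceCall(ConsequenceCategory.NTERM_CHANGE, delta, uorfs)
    if p >= shorter:
        if delta < 0:
            return ConsequenceCall(ConsequenceCategory.CTERM_TRUNCATION, delta, uorfs)
        return ConsequenceCall(
            ConsequenceCategory.INTERNAL_INSERTION, delta, uorfs, "C-terminal extension"
        )
    if delta > 0 and p + s >= len(pep_r):
        return ConsequenceCall(ConsequenceCategory.INTERNAL_INSERTION, delta, uorfs)
    if delta < 0 and p + s >= len(pep_n):
        return ConsequenceCall(
            ConsequenceCategory.INTERNAL_INSERTION, delta, uorfs, "interior deletion"
        )
    if s == 0 and p > 0 and delta < 0:
        return ConsequenceCall(ConsequenceCategory.CTERM_TRUNCATION, delta, uorfs)
    if s > 0 and p == 0:
        return ConsequenceCall(ConsequenceCategory.NTERM_CHANGE, delta, uorfs)
    return ConsequenceCall(ConsequenceCategory.FRAME_DISRUPTION, delta, uorfs)


def scan_proline_rich(peptide: str, window: int = 10, min_fraction: float = 0.5) -> list[int]:
    """Offsets of sliding windows with a proline fraction >= min_fraction.

    Windows containing ``X`` (unknown residue) are skipped.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    hits = []
    for i in range(len(peptide) - window + 1):
        w = peptide[i : i + window]
        if "X" in w:
            continue
        if w.count("P") / window >= min_fraction:
            hits.append(i)
    return hits


_G4_RE = re.compile(r"G{3,}(?:[ACGT]{1,7}G{3,}){3}")


def scan_g_quadruplex(sequence: str) -> list[tuple[int, int]]:
    """Non-overlapping canonical G-quadruplex motifs, leftmost first.

    The canonical motif is four runs of >= 3 guanines separated by
    loops of 1-7 non-N nucleotides.  Returns [start, end) offsets.
    """
    return [(m.start(), m.end()) for m in _G4_RE.finditer(sequence.upper())]
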