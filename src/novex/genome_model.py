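"""Coordinate-aware gene models and I/O.

The in-memory substrate for everything downstream: genomic intervals,
exons, transcript models, annotation sets with interval indexes, and
splice junctions, plus readers/writers for GTF, junction BED6, FASTA and
TSV count tables.

Coordinate conventions
----------------------
External files and all reports use **1-based inclusive** coordinates
(the GTF convention, and the convention of genome-browser position
strings like ``chr11:74467029-74467303``).  Algorithms that slice
sequences use the 0-based half-open view exposed by
:attr:`GenomicInterval.start0` / :attr:`GenomicInterval.end0`; the
conversion happens only at those accessors, never inside parsers or
writers.

Junction BED6 files describe the **intron** as a 0-based half-open span
(columns 2-3), with the score column carrying spliced-read support.  On
read this is converted to the 1-based donor/acceptor representation used
throughout: ``donor`` is the last exonic base of the genomically left
exon and ``acceptor`` the first exonic base of the right exon, so a BED
line ``chr1  200  299`` becomes ``donor=200, acceptor=300``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "ExonRecord",
    "TranscriptModel",
    "AnnotationSet",
    "SpliceJunction",
    "GtfParseError",
    "JunctionParseError",
    "interval_length",
    "read_gtf",
    "write_gtf",
    "read_junctions",
    "write_junctions",
    "merge_junctions",
    "annotated_junctions",
    "read_fasta",
    "write_fasta",
    "fetch_sequence",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
]


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; message names the line number."""


class JunctionParseError(ValueError):
    """Raised for a malformed or inconsistent junction BED record."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval with strand.

    ``length == end - start + 1``, matching the length column of a
    genome-browser exon table computed from its position string.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    # -- 0-based half-open view (for sequence slicing / interval trees) --
    @property
    def start0(self) -> int:
        return self.start - 1

    @property
    def end0(self) -> int:
        return self.end

    @classmethod
    def from_zero_based(cls, chrom: str, start0: int, end0: int, strand: str = ".") -> "GenomicInterval":
        return cls(chrom, start0 + 1, end0, strand)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    _POSITION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)(?P<strand>[+-])?$")

    @classmethod
    def from_position_string(cls, text: str) -> "GenomicInterval":
        """Parse ``chrN:start-end`` with an optional trailing strand sign."""
        m = cls._POSITION_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse position string {text!r}")
        return cls(m["chrom"], int(m["start"]), int(m["end"]), m["strand"] or ".")

    def position_string(self, with_strand: bool = False) -> str:
        s = f"{self.chrom}:{self.start}-{self.end}"
        if with_strand and self.strand in "+-":
            s += self.strand
        return s


def interval_length(iv: GenomicInterval) -> int:
    """Length of a 1-based inclusive interval: ``end - start + 1``."""
    return iv.length


@dataclass(frozen=True)
class ExonRecord:
    """An exon with its ordinal within the transcript (1 = 5'-most)."""

    interval: GenomicInterval
    rank: int

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("exon rank must be >= 1")


@dataclass(frozen=True)
class SpliceJunction:
    """A splice junction in 1-based exonic-boundary representation.

    ``donor`` is the last base of the genomically left flanking exon and
    ``acceptor`` the first base of the right flanking exon; the intron
    is ``[donor+1, acceptor-1]`` and must be at least one base long.
    For minus-strand transcripts the biological donor/acceptor roles are
    swapped, but junction identity is purely genomic.
    """

    chrom: str
    donor: int
    acceptor: int
    strand: str = "."
    read_support: int = 0

    def __post_init__(self) -> None:
        if self.acceptor <= self.donor + 1:
            raise ValueError(
                f"acceptor ({self.acceptor}) must exceed donor+1 ({self.donor + 1}); intron length >= 1"
            )
        if self.read_support < 0:
            raise ValueError("read_support must be nonnegative")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.donor, self.acceptor, self.strand)

    @property
    def intron(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.donor + 1, self.acceptor - 1, self.strand)


class TranscriptModel:
    """A multi-exon transcript: ordered exons on one chromosome/strand.

    Exons are stored in transcript (5'->3') rank order; for minus-strand
    transcripts rank 1 is the genomically rightmost exon.  Introns are
    the gaps between genomically consecutive exons and must be >= 1 bp.
    """

    __slots__ = ("id", "gene_id", "exons", "source")

    def __init__(self, id: str, gene_id: str, exons: Sequence[ExonRecord], source: str = "assembled"):
        if not exons:
            raise ValueError("transcript needs at least one exon")
        exons = tuple(sorted(exons, key=lambda e: e.rank))
        ranks = [e.rank for e in exons]
        if ranks != list(range(1, len(exons) + 1)):
            raise ValueError(f"exon ranks must be consecutive from 1, got {ranks}")
        chroms = {e.interval.chrom for e in exons}
        strands = {e.interval.strand for e in exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError("all exons must share chrom and strand")
        genomic = sorted(exons, key=lambda e: e.interval.start)
        for a, b in zip(genomic, genomic[1:]):
            if b.interval.start <= a.interval.end + 1:
                raise ValueError(
                    f"exons of {id} overlap or abut: {a.interval} / {b.interval} (intron length must be >= 1)"
                )
        strand = exons[0].interval.strand
        expected = genomic if strand != "-" else genomic[::-1]
        if list(exons) != expected:
            raise ValueError(f"exon ranks of {id} do not follow 5'->3' transcript orientation")
        self.id = id
        self.gene_id = gene_id
        self.exons = exons
        self.source = source

    @classmethod
    def from_intervals(
        cls,
        id: str,
        gene_id: str,
        chrom: str,
        strand: str,
        spans: Iterable[tuple[int, int]],
        source: str = "assembled",
    ) -> "TranscriptModel":
        """Build from (start, end) 1-based pairs; ranks assigned by strand."""
        ivs = sorted(GenomicInterval(chrom, s, e, strand) for s, e in spans)
        if strand == "-":
            ivs = ivs[::-1]
        exons = [ExonRecord(iv, i + 1) for i, iv in enumerate(ivs)]
        return cls(id, gene_id, exons, source)

    @property
    def chrom(self) -> str:
        return self.exons[0].interval.chrom

    @property
    def strand(self) -> str:
        return self.exons[0].interval.strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exons_genomic(self) -> tuple[ExonRecord, ...]:
        return tuple(sorted(self.exons, key=lambda e: e.interval.start))

    @property
    def span(self) -> GenomicInterval:
        g = self.exons_genomic
        return GenomicInterval(self.chrom, g[0].interval.start, g[-1].interval.end, self.strand)

    def junctions(self) -> tuple[SpliceJunction, ...]:
        """Junctions between genomically consecutive exons (no support)."""
        g = self.exons_genomic
        return tuple(
            SpliceJunction(self.chrom, a.interval.end, b.interval.start, self.strand)
            for a, b in zip(g, g[1:])
        )

    def intron_chain(self) -> tuple:
        return tuple((j.donor, j.acceptor) for j in self.junctions())

    def __eq__(self, other) -> bool:
        if not isinstance(other, TranscriptModel):
            return NotImplemented
        return (
            self.id == other.id
            and self.gene_id == other.gene_id
            and self.exons == other.exons
            and self.source == other.source
        )

    def __hash__(self) -> int:
        return hash((self.id, self.gene_id, self.exons))

    def __repr__(self) -> str:
        return f"TranscriptModel({self.id!r}, {self.gene_id!r}, {self.n_exons} exons, {self.span.position_string(True)})"


def _strand_keys(j: SpliceJunction) -> tuple:
    """Keys a junction can match under the wildcard-strand rule."""
    base = (j.chrom, j.donor, j.acceptor)
    if j.strand == ".":
        return (base + ("+",), base + ("-",), base + (".",))
    return (base + (j.strand,), base + (".",))


class AnnotationSet:
    """A collection of transcript models with coordinate indexes.

    Indexes (gene spans, exon intervals, the annotated junction set) are
    derived purely from the transcript collection, so rebuilding them is
    idempotent.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel], label: str = "annotation"):
        self.transcripts = tuple(transcripts)
        self.label = label
        self._build_indexes()

    def _build_indexes(self) -> None:
        gene_bounds: dict[tuple[str, str], list[int]] = {}
        self.exon_index: dict[str, IntervalTree] = {}
        juncs: dict[tuple, SpliceJunction] = {}
        chains: set[tuple] = set()
        single: set[tuple] = set()
        for t in self.transcripts:
            b = gene_bounds.setdefault((t.chrom, t.gene_id), [t.span.start, t.span.end, t.strand])
            b[0] = min(b[0], t.span.start)
            b[1] = max(b[1], t.span.end)
            tree = self.exon_index.setdefault(t.chrom, IntervalTree())
            for e in t.exons:
                tree.addi(e.interval.start0, e.interval.end0, (t.gene_id, t.id, e.rank))
            for j in t.junctions():
                juncs.setdefault(j.key, j)
            if t.n_exons > 1:
                chains.add((t.chrom, t.strand, t.intron_chain()))
            else:
                iv = t.exons[0].interval
                single.add((t.chrom, t.strand, iv.start, iv.end))
        self.gene_index: dict[str, IntervalTree] = {}
        self.gene_spans: dict[str, GenomicInterval] = {}
        for (chrom, gid), (s, e, strand) in gene_bounds.items():
            self.gene_index.setdefault(chrom, IntervalTree()).addi(s - 1, e, gid)
            self.gene_spans[gid] = GenomicInterval(chrom, s, e, strand)
        self.junction_set: dict[tuple, SpliceJunction] = juncs
        self._chains = chains
        self._single_exact = single

    def rebuild(self) -> None:
        self._build_indexes()

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)

    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.gene_spans)

    def junction_annotated(self, j: SpliceJunction) -> bool:
        """Strand-aware membership; unstranded matches either strand."""
        return any(k in self.junction_set for k in _strand_keys(j))

    def has_intron_chain(self, t: TranscriptModel) -> bool:
        if t.n_exons > 1:
            for strand in ("+", "-", ".") if t.strand == "." else (t.strand, "."):
                if (t.chrom, strand, t.intron_chain()) in self._chains:
                    return True
            return False
        iv = t.exons[0].interval
        for strand in ("+", "-", ".") if t.strand == "." else (t.strand, "."):
            if (t.chrom, strand, iv.start, iv.end) in self._single_exact:
                return True
        return False

    def overlapping_exons(self, iv: GenomicInterval) -> list:
        tree = self.exon_index.get(iv.chrom)
        if tree is None:
            return []
        return sorted(tree.overlap(iv.start0, iv.end0))

    def overlapping_genes(self, iv: GenomicInterval) -> list[str]:
        tree = self.gene_index.get(iv.chrom)
        if tree is None:
            return []
        return sorted({hit.data for hit in tree.overlap(iv.start0, iv.end0)})

    def genes_containing(self, iv: GenomicInterval) -> list[str]:
        return sorted(
            gid for gid in self.overlapping_genes(iv) if self.gene_spans[gid].contains(iv)
        )


def annotated_junctions(ann: AnnotationSet) -> set[SpliceJunction]:
    """All junctions between consecutive exon pairs, deduplicated."""
    return set(ann.junction_set.values())


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

# quoted (gene_id "g1";) or unquoted (gene_id g1;) attribute dialects
_ATTR_RE = re.compile(r'(\w+)\s+(?:"([^"]*)"|([^;\s]+))\s*;?')


def _parse_attributes(text: str) -> dict[str, str]:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3) for m in _ATTR_RE.finditer(text)}


def read_gtf(path, source_label: str = "assembled") -> AnnotationSet:
    """Read exon features from a GTF file into an :class:`AnnotationSet`.

    Both quoted and unquoted attribute dialects are accepted.  A
    malformed line raises :class:`GtfParseError` naming the line number;
    an exon feature lacking ``transcript_id`` is skipped with a warning.
    """
    exons: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"{path}: line {lineno}: expected 9 tab-separated columns, got {len(fields)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise GtfParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if strand not in STRANDS:
                raise GtfParseError(f"{path}: line {lineno}: bad strand {strand!r}")
            a = _parse_attributes(attrs)
            tid = a.get("transcript_id")
            if not tid:
                logger.warning("%s: line %d: exon without transcript_id skipped", path, lineno)
                continue
            gid = a.get("gene_id", tid)
            exons.setdefault(tid, []).append((start_i, end_i))
            meta.setdefault(tid, (gid, chrom, strand))
    transcripts = []
    for tid, spans in exons.items():
        gid, chrom, strand = meta[tid]
        transcripts.append(TranscriptModel.from_intervals(tid, gid, chrom, strand, spans, source_label))
    transcripts.sort(key=lambda t: (t.chrom, t.span.start, t.id))
    return AnnotationSet(transcripts, label=source_label)


def write_gtf(ann_or_transcripts, path, source: str = "novex", quoted: bool = True) -> None:
    """Write exon features in GTF; attributes quoted or bare by dialect."""
    transcripts = list(ann_or_transcripts)
    fmt = 'gene_id "{g}"; transcript_id "{t}";' if quoted else "gene_id {g}; transcript_id {t};"
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.span.start, t.id)):
            for e in t.exons_genomic:
                iv = e.interval
                fh.write(
                    "\t".join(
                        [
                            iv.chrom,
                            source,
                            "exon",
                            str(iv.start),
                            str(iv.end),
                            ".",
                            iv.strand,
                            ".",
                            fmt.format(g=t.gene_id, t=t.id),
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Junction BED6 I/O
# ---------------------------------------------------------------------------

def merge_junctions(junctions: Iterable[SpliceJunction]) -> list[SpliceJunction]:
    """Merge duplicate junction records by summing read support."""
    merged: dict[tuple, SpliceJunction] = {}
    for j in junctions:
        prev = merged.get(j.key)
        if prev is None:
            merged[j.key] = j
        else:
            merged[j.key] = replace(prev, read_support=prev.read_support + j.read_support)
    return sorted(merged.values(), key=lambda j: j.key)


def read_junctions(path) -> list[SpliceJunction]:
    """Read a BED6 junction file (columns 2-3 = intron, 0-based half-open).

    Duplicate records are merged by summing support.  Negative scores
    raise :class:`JunctionParseError`; records whose intron would be
    empty are rejected with a warning.
    """
    out: list[SpliceJunction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise JunctionParseError(f"{path}: line {lineno}: expected >= 6 columns")
            chrom, bed_start, bed_end, _name, score, strand = fields[:6]
            support = int(float(score))
            if support < 0:
                raise JunctionParseError(f"{path}: line {lineno}: negative read support {support}")
            donor = int(bed_start)  # last exonic base, 1-based == intron start, 0-based
            acceptor = int(bed_end) + 1
            if acceptor <= donor + 1:
                logger.warning("%s: line %d: empty or inverted intron rejected", path, lineno)
                continue
            out.append(SpliceJunction(chrom, donor, acceptor, strand if strand in STRANDS else ".", support))
    return merge_junctions(out)


def write_junctions(junctions: Iterable[SpliceJunction], path) -> None:
    with open(path, "w") as fh:
        for i, j in enumerate(sorted(junctions, key=lambda j: j.key)):
            fh.write(
                f"{j.chrom}\t{j.donor}\t{j.acceptor - 1}\tJ{i + 1}\t{j.read_support}\t{j.strand}\n"
            )


# ---------------------------------------------------------------------------
# FASTA and TSV helpers
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a whole FASTA into a plain dict (small genomes only)."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence before first header")
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fetch_sequence(genome, chrom: str, start0: int, end0: int) -> str:
    """Slice [start0, end0) from a dict of strings or a pyfaidx.Fasta."""
    contig = genome[chrom]
    piece = contig[start0:end0]
    return str(piece).upper()


def read_counts(path) -> pd.DataFrame:
    """Counts TSV: first column feature_id, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative counts")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate feature ids")
    return df.astype(int)


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_design(path) -> pd.Series:
    """Design TSV: two columns, sample_id and group."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: design file needs sample_id and group columns")
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")
    if s.nunique() < 2:
        raise ValueError(f"{path}: design must contain at least two groups")
    return s


def write_design(design: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": design.index, "group": design.values}).to_csv(path, sep="\t", index=False)
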