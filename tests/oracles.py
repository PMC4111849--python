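"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive: direct loops over all pairs, a
hand-written codon table, a recursive pattern matcher.  None of it
shares code with the package beyond the public data types, so agreement
between the two routes is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np

from novex.discovery import TranscriptClass
from novex.genome_model import AnnotationSet, SpliceJunction, TranscriptModel

# ---------------------------------------------------------------------------
# transcript classification
# ---------------------------------------------------------------------------


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _strand_compatible(a: str, b: str) -> bool:
    return a == "." or b == "." or a == b


def classify_oracle(t: TranscriptModel, ann: AnnotationSet) -> TranscriptClass:
    """All-pairs scan over every annotated transcript and exon."""
    refs = [r for r in ann.transcripts if r.chrom == t.chrom]
    # KNOWN: identical intron chain (multi-exon) or exact exon (single)
    for r in refs:
        if not _strand_compatible(t.strand, r.strand):
            continue
        if t.n_exons > 1 and r.n_exons > 1 and t.intron_chain() == r.intron_chain():
            return TranscriptClass.KNOWN
        if t.n_exons == 1 and r.n_exons == 1:
            ti, ri = t.exons[0].interval, r.exons[0].interval
            if (ti.start, ti.end) == (ri.start, ri.end):
                return TranscriptClass.KNOWN
    # EXONIC_OVERLAP: any exon/exon overlap regardless of strand
    for r in refs:
        for re_ in r.exons:
            for te in t.exons:
                if _spans_overlap(
                    (te.interval.start, te.interval.end),
                    (re_.interval.start, re_.interval.end),
                ):
                    return TranscriptClass.EXONIC_OVERLAP
    # INTRONIC: span inside some gene span
    gene_spans: dict[str, list[int]] = {}
    for r in refs:
        s = gene_spans.setdefault(r.gene_id, [r.span.start, r.span.end])
        s[0] = min(s[0], r.span.start)
        s[1] = max(s[1], r.span.end)
    span = t.span
    for lo, hi in gene_spans.values():
        if lo <= span.start and span.end <= hi:
            return TranscriptClass.INTRONIC
    return TranscriptClass.INTERGENIC


# ---------------------------------------------------------------------------
# novel exon deduction
# ---------------------------------------------------------------------------


def deduce_exons_oracle(
    junctions: list[SpliceJunction], ann: AnnotationSet, min_support: int
) -> set[tuple[str, int, int]]:
    """O(introns x junctions^2) scan; returns exon coordinate triples."""
    annotated = set()
    for t in ann.transcripts:
        for j in t.junctions():
            annotated.add((j.chrom, j.donor, j.acceptor, j.strand))

    def is_annotated(j: SpliceJunction) -> bool:
        strands = ("+", "-", ".") if j.strand == "." else (j.strand, ".")
        return any((j.chrom, j.donor, j.acceptor, s) in annotated for s in strands)

    exons = set()
    for t in ann.transcripts:
        g = sorted(t.exons, key=lambda e: e.interval.start)
        for a, b in zip(g, g[1:]):
            for j1 in junctions:
                for j2 in junctions:
                    if j1.chrom != t.chrom or j2.chrom != t.chrom:
                        continue
                    if not (_strand_compatible(j1.strand, t.strand) and _strand_compatible(j2.strand, t.strand)):
                        continue
                    if j1.read_support < min_support or j2.read_support < min_support:
                        continue
                    if is_annotated(j1) or is_annotated(j2):
                        continue
                    if j1.donor != a.interval.end or j2.acceptor != b.interval.start:
                        continue
                    if not (j1.acceptor < b.interval.start and j2.donor > a.interval.end):
                        continue
                    if j2.donor < j1.acceptor:
                        continue
                    exons.add((t.chrom, j1.acceptor, j2.donor))
    return exons


# ---------------------------------------------------------------------------
# translation / ORF / uORF
# ---------------------------------------------------------------------------

_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def translate_oracle(seq: str) -> str:
    """Hand-rolled standard-code translation; N codons become X."""
    pep = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        pep.append(CODON_TABLE.get(codon, "X"))
    return "".join(pep)


def main_orf_oracle(seq: str, min_codons: int) -> tuple[int, int, str] | None:
    """Longest stopped ATG ORF, ties 5'-most; falls back to stop-less.

    Returns (start, end_exclusive_with_stop, peptide) or None.
    """
    stops = {"TAA", "TAG", "TGA"}
    best = None  # (peptide_len, start, end, pep, has_stop)
    best_open = None
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        end = None
        for i in range(start + 3, len(seq) - 2, 3):
            if seq[i : i + 3] in stops:
                end = i + 3
                break
        if end is not None:
            pep = translate_oracle(seq[start : end - 3])
            if len(pep) >= min_codons and (best is None or len(pep) > best[0]):
                best = (len(pep), start, end, pep)
        else:
            n = (len(seq) - start) // 3
            pep = translate_oracle(seq[start : start + 3 * n])
            if len(pep) >= min_codons and (best_open is None or len(pep) > best_open[0]):
                best_open = (len(pep), start, start + 3 * n, pep)
    pick = best if best is not None else best_open
    return None if pick is None else (pick[1], pick[2], pick[3])


def count_uorfs_oracle(seq: str, main_start: int, min_codons: int) -> int:
    stops = {"TAA", "TAG", "TGA"}
    n = 0
    for start in range(max(main_start, 0)):
        if seq[start : start + 3] != "ATG":
            continue
        for i in range(start + 3, len(seq) - 2, 3):
            if seq[i : i + 3] in stops:
                if i + 3 <= main_start and (i + 3 - start) // 3 >= min_codons:
                    n += 1
                break
    return n


# ---------------------------------------------------------------------------
# motif scans
# ---------------------------------------------------------------------------


def proline_windows_oracle(peptide: str, window: int, min_fraction: float) -> list[int]:
    out = []
    for i in range(len(peptide) - window + 1):
        w = peptide[i : i + window]
        if "X" in w:
            continue
        if sum(1 for c in w if c == "P") / window >= min_fraction:
            out.append(i)
    return out


def _g4_match_end(seq: str, pos: int, tracts_left: int) -> int | None:
    """Greedy-with-backtracking matcher for G{3,}([ACGT]{1,7}G{3,}){3}.

    Mirrors the leftmost-greedy semantics of a backtracking regex
    engine by trying longer G runs and loops first.
    """
    run = 0
    while pos + run < len(seq) and seq[pos + run] == "G":
        run += 1
    if run < 3:
        return None
    for g in range(run, 2, -1):  # greedy: longest G run first
        after = pos + g
        if tracts_left == 0:
            return after
        for loop in range(7, 0, -1):  # greedy loop
            nxt = after + loop
            if nxt + 3 > len(seq):
                continue
            if any(c not in "ACGT" for c in seq[after:nxt]):
                continue
            end = _g4_match_end(seq, nxt, tracts_left - 1)
            if end is not None:
                return end
    return None


def g4_scan_oracle(seq: str) -> list[tuple[int, int]]:
    """Non-overlapping leftmost G-quadruplex matches."""
    seq = seq.upper()
    out = []
    pos = 0
    while pos < len(seq):
        end = _g4_match_end(seq, pos, 3)
        if end is not None:
            out.append((pos, end))
            pos = end
        else:
            pos += 1
    return out


# ---------------------------------------------------------------------------
# permutation reference for the exon-usage statistic
# ---------------------------------------------------------------------------


def permutation_usage_p(
    exon: np.ndarray, other: np.ndarray, cond2: np.ndarray, n_perm: int, rng: np.random.Generator
) -> float:
    """Permutation p-value for the pooled inclusion-proportion difference.

    Relabels samples uniformly at random and compares the absolute
    pooled proportion difference against the observed one.
    """

    def stat(mask: np.ndarray) -> float:
        n = exon + other
        p1 = exon[~mask].sum() / n[~mask].sum()
        p2 = exon[mask].sum() / n[mask].sum()
        return abs(p2 - p1)

    obs = stat(cond2)
    k = int(cond2.sum())
    idx = np.arange(len(cond2))
    hits = 0
    for _ in range(n_perm):
        pick = rng.choice(idx, size=k, replace=False)
        mask = np.zeros(len(cond2), dtype=bool)
        mask[pick] = True
        hits += stat(mask) >= obs - 1e-12
    return (hits + 1) / (n_perm + 1)
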