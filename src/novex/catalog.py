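"""Bundled mm9 catalogs of tissue-enriched novel transcripts and exons.

Two small reference tables ship with the package:

* ``novel_transcripts_mm9.tsv`` — 32 testis- and 2 liver-enriched
  putative novel intergenic transcripts (tNT/lNT), with locus, exon
  count and the min/max p-value over all pairwise tissue comparisons.
* ``novel_exons_mm9.tsv`` — 13 heart- (hNE) and 26 testis-enriched
  (tNE) novel cassette exons with mm9 position, length, host gene and
  the predicted consequence of exon inclusion.

A handful of published insertion peptides are exposed as constants;
they anchor the residue-counting and phosphosite-position conventions
used by the consequence module.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genome_model import GenomicInterval

# Serine-rich insertion encoded by the heart-enriched novel exon of Csde1
# (46 residues; Ser-32 and Thr-34 are predicted PKC phosphosites).
CSDE1_INSERTION_PEPTIDE = "MENMLTVSSDPQPTPAAPPSLSLPLSSSSTSSWTKKQKRTPTYQRS"

# Insertion encoded by the testis-enriched novel exon of Vapa: 38
# residues, or 41 with the optional C-terminal VKQ extension carried by
# the second assembled variant (9-bp longer).
VAPA_INSERTION_PEPTIDE = "GKTPPGIASTVASLSSVSSAVATPASYHLKNDPRELKE"
VAPA_INSERTION_EXTENSION = "VKQ"

# Proline-rich stretches of the heart-enriched Sorbs1 novel exon.
SORBS1_PROLINE_MOTIFS = ("PPPAPPPDPP", "PPCLPFP", "PKPYIPPSTP", "PSLPTPTSVP")


def _load(name: str) -> pd.DataFrame:
    with resources.files("novex.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def novel_exon_catalog() -> pd.DataFrame:
    """The 39-row novel exon table with parsed interval columns."""
    df = _load("novel_exons_mm9.tsv")
    ivs = []
    for pos, strand in zip(df["position"], df["strand"]):
        base = GenomicInterval.from_position_string(pos)
        ivs.append(GenomicInterval(base.chrom, base.start, base.end, strand))
    df = df.copy()
    df["interval"] = ivs
    return df


def novel_transcript_catalog() -> pd.DataFrame:
    """The 34-row novel transcript table (position strings keep strand)."""
    df = _load("novel_transcripts_mm9.tsv")
    df = df.copy()
    df["interval"] = [GenomicInterval.from_position_string(p) for p in df["position"]]
    return df
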