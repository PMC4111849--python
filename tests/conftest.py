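"""Shared fixtures: a small ground-truthed synthetic bundle and helpers."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from novex.pipeline import PipelineConfig
from novex.simulate import SyntheticTruth, generate_bundle

SEED = 20140713


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory) -> tuple[Path, SyntheticTruth]:
    """A compact synthetic bundle: 24 genes, 5 + 5 planted novelties."""
    outdir = tmp_path_factory.mktemp("bundle")
    truth = generate_bundle(
        outdir,
        seed=SEED,
        n_genes=24,
        n_novel_transcripts=5,
        n_novel_exons=5,
        n_contigs=2,
        contig_length=350_000,
    )
    return outdir, truth


@pytest.fixture()
def small_config(small_bundle, tmp_path) -> tuple[PipelineConfig, SyntheticTruth]:
    outdir, truth = small_bundle
    cfg = PipelineConfig(
        reference_a=outdir / "reference_A.gtf",
        reference_b=outdir / "reference_B.gtf",
        assembled=outdir / "assembled.gtf",
        junctions=outdir / "junctions.bed",
        counts=outdir / "counts.tsv",
        design=outdir / "design.tsv",
        genome=outdir / "genome.fa",
        usage_exon=outdir / "usage_exon.tsv",
        usage_other=outdir / "usage_other.tsv",
        usage_design=outdir / "usage_design.tsv",
        outdir=tmp_path / "out",
    )
    return cfg, truth
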