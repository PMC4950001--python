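"""Shared fixtures: transcript factories, a brute-force classifier oracle,
and one session-wide synthetic dataset."""

from __future__ import annotations

import numpy as np
import pytest

from lincpipe.genomic_io import Annotation, GenomicInterval, TranscriptModel
from lincpipe.synthetic_data import simulate_all


def make_tx(
    tid: str,
    chrom: str,
    strand: str,
    exons: list[tuple[int, int]],
    biotype: str = "unknown",
    gene: str | None = None,
    fpkm: dict | None = None,
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene or tid,
        exons=tuple(GenomicInterval(chrom, a, b, strand) for a, b in exons),
        biotype=biotype,
        fpkm=fpkm or {},
    )


def brute_classify(t, annotation, antisense_mode="span"):
    """O(n*m) positional classifier: linear scans, no interval index.

    Independent of the indexed implementation; same fixed precedence
    pseudogene > antisense > lincRNA.
    """
    for g in annotation.transcripts():
        if g.chrom != t.chrom or g.biotype != "pseudogene":
            continue
        if any(e.start < g.end and g.start < e.end for e in t.exons):
            return "pseudogene"
    for g in annotation.transcripts():
        if g.chrom != t.chrom or g.biotype != "protein_coding":
            continue
        if not (
            t.strand in "+-" and g.strand in "+-" and g.strand != t.strand
        ):
            continue
        if antisense_mode == "span":
            if any(e.start < g.end and g.start < e.end for e in t.exons):
                return "antisense"
        else:
            if any(
                e.start < ge.end and ge.start < e.end
                for e in t.exons
                for ge in g.exons
            ):
                return "antisense"
    return "lincRNA"


def random_transcripts(rng: np.random.Generator, n: int, chrom_length: int, chrom="chr1"):
    """Unconstrained random transcripts (may overlap anything) for oracle tests."""
    out = []
    for i in range(n):
        n_exons = int(rng.integers(1, 5))
        pos = int(rng.integers(0, chrom_length - 20_000))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(100, 600))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(50, 2000))
        out.append(
            make_tx(f"R{i:04d}", chrom, str(rng.choice(["+", "-"])), exons)
        )
    return out


@pytest.fixture
def tx():
    return make_tx


@pytest.fixture
def oracle_classify():
    return brute_classify


@pytest.fixture(scope="session")
def synth_dataset(tmp_path_factory):
    """One packaged synthetic dataset shared by pipeline/acceptance tests."""
    outdir = tmp_path_factory.mktemp("synth")
    paths = simulate_all(outdir, seed=17)
    return paths
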