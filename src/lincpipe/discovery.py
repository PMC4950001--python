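"""Candidate lncRNA discovery: the filter chain over assembled transfrags.

Transfrags are kept when they (i) share no exonic base with a
protein-coding exon on the same strand, (ii) are at least ``min_length``
nt of spliced sequence, (iii) have at least ``min_exons`` exons and
(iv) reach ``min_fpkm`` in at least one condition. Each rejected
transfrag carries exactly one primary reason — the first failing filter
in that fixed order. All thresholds are inclusive (>=).
"""

from __future__ import annotations

from dataclasses import dataclass

from lincpipe.genomic_io import Annotation, TranscriptModel

__all__ = [
    "DiscoveryConfig",
    "FeatureSummary",
    "REASONS",
    "filter_transfrags",
    "summarize_features",
]

#: fixed filter order; the first failing filter names the rejection reason
REASONS = ("coding_overlap", "length", "exon_count", "expression")


@dataclass(frozen=True)
class DiscoveryConfig:
    """Thresholds of the discovery filter chain.

    min_fpkm applies to the maximum per-condition FPKM so that
    stimulus-specific transcripts silent at baseline are retained.
    """

    min_fpkm: float = 1.0
    min_length: int = 200
    min_exons: int = 1
    require_no_coding_overlap_same_strand: bool = True

    def __post_init__(self) -> None:
        if self.min_fpkm < 0 or self.min_length < 0 or self.min_exons < 1:
            raise ValueError("thresholds out of range")


@dataclass(frozen=True)
class FeatureSummary:
    mean_fpkm: float
    mean_length_kb: float
    mean_exons: float
    n: int


def overlaps_coding_exon_same_strand(
    t: TranscriptModel, annotation: Annotation
) -> bool:
    """True when any exon of ``t`` shares >= 1 bp with a protein-coding exon
    on the same strand."""
    for g in annotation.overlapping(t.chrom, t.start, t.end):
        if g.biotype != "protein_coding" or g.strand != t.strand:
            continue
        if t.exonic_overlap(g) > 0:
            return True
    return False


def filter_transfrags(
    transfrags: list[TranscriptModel],
    annotation: Annotation,
    cfg: DiscoveryConfig = DiscoveryConfig(),
) -> tuple[list[TranscriptModel], list[tuple[TranscriptModel, str]]]:
    """Partition transfrags into (kept, rejected-with-reason).

    Transfrags on chromosomes absent from the annotation are filtered
    normally (the coding-overlap test is vacuously passed there).
    """
    kept: list[TranscriptModel] = []
    rejected: list[tuple[TranscriptModel, str]] = []
    for t in transfrags:
        reason = _first_failure(t, annotation, cfg)
        if reason is None:
            kept.append(t)
        else:
            rejected.append((t, reason))
    return kept, rejected


def _first_failure(
    t: TranscriptModel, annotation: Annotation, cfg: DiscoveryConfig
) -> str | None:
    if cfg.require_no_coding_overlap_same_strand and overlaps_coding_exon_same_strand(
        t, annotation
    ):
        return "coding_overlap"
    if t.length < cfg.min_length:
        return "length"
    if t.n_exons < cfg.min_exons:
        return "exon_count"
    if t.max_fpkm < cfg.min_fpkm:
        return "expression"
    return None


def summarize_features(transcripts: list[TranscriptModel]) -> FeatureSummary:
    """Arithmetic means of max-condition FPKM, spliced length (kb) and exon count."""
    if not transcripts:
        raise ValueError("summarize_features: empty input has no mean")
    n = len(transcripts)
    return FeatureSummary(
        mean_fpkm=sum(t.max_fpkm for t in transcripts) / n,
        mean_length_kb=sum(t.length for t in transcripts) / n / 1000.0,
        mean_exons=sum(t.n_exons for t in transcripts) / n,
        n=n,
    )
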