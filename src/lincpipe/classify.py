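"""Positional classification, novelty against catalogs, and eRNA overlap.

A candidate lncRNA is classified with fixed precedence
``pseudogene > antisense > lincRNA``:

* **pseudogene** — any exon overlaps the genomic span of an annotated
  pseudogene (either strand);
* **antisense** — any exon overlaps a protein-coding gene on the
  opposite strand; by default against the gene's full genomic span,
  since antisense transcripts commonly overlap introns (an exon-only
  mode is available);
* **lincRNA** — neither of the above (intergenic).

Novelty is decided by same-strand exonic reciprocal overlap against one
or more reference catalogs; a transcript matching no catalog is novel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from intervaltree import IntervalTree

from lincpipe.genomic_io import Annotation, GenomicInterval, TranscriptModel

__all__ = [
    "CLASSES",
    "ClassifiedLncRNA",
    "classify_position",
    "match_catalog",
    "classify_novelty",
    "erna_overlap_fraction",
    "class_breakdown",
    "classify_all",
]

CLASSES = ("lincRNA", "antisense", "pseudogene")


@dataclass
class ClassifiedLncRNA:
    transcript: TranscriptModel
    lnc_class: str
    novelty: str = "novel"
    matched_catalogs: set[str] = field(default_factory=set)
    erna_overlap: bool = False

    def __post_init__(self) -> None:
        if self.lnc_class not in CLASSES:
            raise ValueError(f"bad class {self.lnc_class!r}")


def _exon_overlaps_span(t: TranscriptModel, g: TranscriptModel) -> bool:
    return any(e.start < g.end and g.start < e.end for e in t.exons)


def classify_position(
    t: TranscriptModel, annotation: Annotation, antisense_mode: str = "span"
) -> str:
    """Assign the positional class of ``t`` against ``annotation``.

    Total function: a transcript on a chromosome with no annotated gene
    is intergenic by vacuity and returns ``lincRNA``.
    """
    if antisense_mode not in ("span", "exon"):
        raise ValueError(f"antisense_mode must be 'span' or 'exon'")
    hits = annotation.overlapping(t.chrom, t.start, t.end)
    for g in hits:
        if g.biotype == "pseudogene" and _exon_overlaps_span(t, g):
            return "pseudogene"
    for g in hits:
        if g.biotype != "protein_coding":
            continue
        if t.strand in ("+", "-") and g.strand in ("+", "-") and g.strand != t.strand:
            if antisense_mode == "span":
                if _exon_overlaps_span(t, g):
                    return "antisense"
            elif t.exonic_overlap(g) > 0:
                return "antisense"
    return "lincRNA"


def match_catalog(
    t: TranscriptModel, catalog: Annotation, min_recip_overlap: float = 0.5
) -> tuple[str, list[str]]:
    """Match ``t`` against one catalog by same-strand exonic reciprocal overlap.

    A catalog transcript matches when the shared exonic bases cover at
    least ``min_recip_overlap`` of *both* transcripts. Returns
    ``("known", matched_ids)`` or ``("novel", [])``.
    """
    if not (0 < min_recip_overlap <= 1):
        raise ValueError("min_recip_overlap must be in (0, 1]")
    matched: list[str] = []
    for c in catalog.overlapping(t.chrom, t.start, t.end):
        if c.strand != t.strand:
            continue
        ov = t.exonic_overlap(c)
        if ov == 0:
            continue
        if min(ov / t.length, ov / c.length) >= min_recip_overlap:
            matched.append(c.transcript_id)
    return ("known" if matched else "novel", sorted(matched))


def classify_novelty(
    t: TranscriptModel,
    catalogs: Mapping[str, Annotation],
    min_recip_overlap: float = 0.5,
) -> tuple[str, set[str]]:
    """Aggregate catalog matching: known iff any catalog matches (union)."""
    tags: set[str] = set()
    for tag, cat in catalogs.items():
        status, _ = match_catalog(t, cat, min_recip_overlap)
        if status == "known":
            tags.add(tag)
    return ("known" if tags else "novel", tags)


def erna_overlap_fraction(
    lncs: list[ClassifiedLncRNA], enhancers: Iterable[GenomicInterval]
) -> tuple[float, dict[str, bool]]:
    """Flag lncRNAs with >= 1 bp exonic overlap with any enhancer interval.

    Strand-blind, since enhancer RNAs are transcribed bidirectionally.
    Mutates ``erna_overlap`` on each entry and returns
    (flagged fraction, per-transcript flags).
    """
    if not lncs:
        raise ValueError("erna_overlap_fraction: empty lncRNA list")
    trees: dict[str, IntervalTree] = {}
    for iv in enhancers:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    flags: dict[str, bool] = {}
    for lnc in lncs:
        t = lnc.transcript
        tree = trees.get(t.chrom)
        hit = bool(tree) and any(tree.overlap(e.start, e.end) for e in t.exons)
        lnc.erna_overlap = hit
        flags[t.transcript_id] = hit
    frac = sum(flags.values()) / len(flags)
    return frac, flags


def _apportion_percent(counts: dict[str, int]) -> dict[str, int]:
    """Integer percentages summing to 100 by largest remainder.

    Ties in remainder go to the rarer class (then alphabetically), the
    convention that keeps small classes visible in a printed breakdown.
    """
    total = sum(counts.values())
    floors = {k: (100 * v) // total for k, v in counts.items()}
    remainders = {k: (100 * v) % total for k, v in counts.items()}  # exact
    short = 100 - sum(floors.values())
    order = sorted(counts, key=lambda k: (-remainders[k], counts[k], k))
    for k in order[:short]:
        floors[k] += 1
    return floors


def class_breakdown(lncs: list[ClassifiedLncRNA]) -> dict:
    """Counts and integer percentages per class, plus novelty tallies."""
    if not lncs:
        raise ValueError("class_breakdown: empty input")
    counts = {c: 0 for c in CLASSES}
    novel = {c: 0 for c in CLASSES}
    for lnc in lncs:
        counts[lnc.lnc_class] += 1
        if lnc.novelty == "novel":
            novel[lnc.lnc_class] += 1
    present = {c: n for c, n in counts.items() if n > 0}
    pct = _apportion_percent(present)
    total = len(lncs)
    return {
        "total": total,
        "counts": counts,
        "percent": {c: pct.get(c, 0) for c in CLASSES},
        "percent_raw": {c: 100.0 * counts[c] / total for c in CLASSES},
        "novel_counts": novel,
        "novel_total": sum(novel.values()),
    }


def classify_all(
    transcripts: list[TranscriptModel],
    annotation: Annotation,
    catalogs: Mapping[str, Annotation] | None = None,
    enhancers: Iterable[GenomicInterval] | None = None,
    min_recip_overlap: float = 0.5,
    antisense_mode: str = "span",
) -> list[ClassifiedLncRNA]:
    """Classify position + novelty (+ eRNA flags when enhancers given)."""
    out: list[ClassifiedLncRNA] = []
    for t in transcripts:
        lnc_class = classify_position(t, annotation, antisense_mode)
        novelty, tags = (
            classify_novelty(t, catalogs, min_recip_overlap)
            if catalogs
            else ("novel", set())
        )
        out.append(ClassifiedLncRNA(t, lnc_class, novelty, tags))
    if out and enhancers is not None:
        erna_overlap_fraction(out, enhancers)
    return out
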