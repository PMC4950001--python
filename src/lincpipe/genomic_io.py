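"""Genomic and tabular I/O with a single internal coordinate convention.

Every coordinate inside the package is 0-based, half-open ``[start, end)``
on the forward genome axis. Conversion happens exactly once, at the I/O
boundary: GTF and browser-style ``chrN:A-B`` locus strings are 1-based
inclusive and are shifted on read/write; BED is already half-open and
passes through unchanged.

GTF attribute parsing is delegated to :func:`gffutils.feature.feature_from_line`;
exon grouping, validation and coordinate conversion live here.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

__all__ = [
    "ParseError",
    "ValidationError",
    "GenomicInterval",
    "TranscriptModel",
    "Annotation",
    "read_gtf",
    "write_gtf",
    "read_bed",
    "write_bed",
    "read_expression_table",
    "write_expression_table",
    "parse_locus",
    "format_locus",
    "normalize_chrom",
]

STRANDS = ("+", "-", ".")
BIOTYPES = ("protein_coding", "pseudogene", "lncRNA", "unknown")

#: annotation attribute values mapped onto the internal biotype vocabulary
_LNC_BIOTYPES = {
    "lncrna",
    "lincrna",
    "antisense",
    "antisense_rna",
    "sense_intronic",
    "sense_overlapping",
    "3prime_overlapping_ncrna",
    "processed_transcript",
    "non_coding",
    "noncoding",
}


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates an invariant (negative FPKM, end < start, ...)."""


def normalize_biotype(raw: str | None) -> str:
    """Map an annotation biotype attribute onto the internal vocabulary.

    Anything containing ``pseudogene`` is a pseudogene; lncRNA-family
    labels collapse to ``lncRNA``; everything unrecognized is ``unknown``.
    """
    if raw is None:
        return "unknown"
    low = raw.strip().lower()
    if "pseudogene" in low:
        return "pseudogene"
    if low == "protein_coding":
        return "protein_coding"
    if low in _LNC_BIOTYPES:
        return "lncRNA"
    return "unknown"


def normalize_chrom(name: str, style: str = "chr") -> str:
    """Force a chromosome name into ``chr``-prefixed or bare style.

    Matching elsewhere in the package is exact string match; this helper
    is the explicit escape hatch for mixed-style inputs.
    """
    if style == "chr":
        return name if name.startswith("chr") else "chr" + name
    if style == "bare":
        return name[3:] if name.startswith("chr") else name
    raise ValueError(f"unknown chromosome style {style!r}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a chromosome strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TranscriptModel:
    """An assembled or annotated transcript: exon chain plus expression.

    Exons must share one chromosome and strand, be sorted in genomic
    order and be non-overlapping. ``fpkm`` maps a condition label to a
    non-negative expression value.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "unknown"
    fpkm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        if not exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"{self.transcript_id}: exons span multiple chromosomes/strands"
            )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"{self.transcript_id}: overlapping exons {a} / {b}"
                )
        if self.biotype not in BIOTYPES:
            raise ValidationError(f"{self.transcript_id}: bad biotype {self.biotype!r}")
        for cond, v in self.fpkm.items():
            if v < 0:
                raise ValidationError(
                    f"{self.transcript_id}: negative FPKM {v} for {cond!r}"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        """Spliced transcript length: sum of exon lengths."""
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        """Strand-aware 5' end ('.' treated as '+')."""
        return self.end if self.strand == "-" else self.start

    @property
    def max_fpkm(self) -> float:
        """Maximum expression over conditions (0.0 when unmeasured)."""
        return max(self.fpkm.values(), default=0.0)

    def shifted(self, offset: int) -> "TranscriptModel":
        """Translate all coordinates by ``offset`` (used by invariance tests)."""
        return replace(
            self,
            exons=tuple(
                GenomicInterval(e.chrom, e.start + offset, e.end + offset, e.strand)
                for e in self.exons
            ),
        )

    def exonic_overlap(self, other: "TranscriptModel") -> int:
        """Base-level exon-vs-exon overlap with another transcript (strand-blind)."""
        if self.chrom != other.chrom:
            return 0
        total = 0
        for a in self.exons:
            for b in other.exons:
                total += a.overlap_length(b)
        return total


class Annotation:
    """A set of transcripts grouped by gene, with an interval index per chromosome.

    The index stores transcript genomic spans; queries return every
    transcript whose span overlaps the query window (identical to a
    linear scan — an invariant the test suite enforces).
    """

    def __init__(
        self, transcripts: Iterable[TranscriptModel] = (), source_tag: str = ""
    ) -> None:
        self.source_tag = source_tag
        self._by_gene: dict[str, list[TranscriptModel]] = {}
        self._by_tid: dict[str, TranscriptModel] = {}
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self._by_tid:
            raise ValidationError(f"duplicate transcript_id {t.transcript_id!r}")
        self._by_tid[t.transcript_id] = t
        self._by_gene.setdefault(t.gene_id, []).append(t)
        self._trees[t.chrom].addi(t.start, t.end, t)

    @property
    def genes(self) -> Mapping[str, list[TranscriptModel]]:
        return self._by_gene

    @property
    def n_genes(self) -> int:
        return len(self._by_gene)

    @property
    def n_transcripts(self) -> int:
        return len(self._by_tid)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_tid

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self._by_tid[transcript_id]

    def transcripts(self) -> Iterator[TranscriptModel]:
        yield from self._by_tid.values()

    def transcripts_of_biotype(self, biotype: str) -> list[TranscriptModel]:
        return [t for t in self._by_tid.values() if t.biotype == biotype]

    def chroms(self) -> set[str]:
        return set(self._trees)

    def overlapping(
        self, chrom: str, start: int, end: int
    ) -> list[TranscriptModel]:
        """Transcripts whose genomic span overlaps ``[start, end)`` on ``chrom``.

        Deterministic order: (span start, transcript_id).
        """
        hits = [iv.data for iv in self._trees[chrom].overlap(start, end)]
        return sorted(hits, key=lambda t: (t.start, t.transcript_id))


# ---------------------------------------------------------------------------
# GTF


def read_gtf(path: str | Path, source_tag: str = "") -> Annotation:
    """Read a GTF file into an :class:`Annotation`.

    Only ``exon`` features are used to build transcripts; 1-based
    inclusive GTF coordinates become internal half-open intervals. The
    biotype is taken from the first of ``gene_type`` / ``gene_biotype`` /
    ``transcript_type`` / ``transcript_biotype`` / ``biotype`` present,
    normalized onto {protein_coding, pseudogene, lncRNA, unknown}.
    """
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}  # tid -> (gene_id, biotype)
    order: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-delimited fields")
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises assorted exceptions
                raise ParseError(f"{path}:{lineno}: malformed GTF line ({exc})")
            if feat.featuretype != "exon":
                continue
            attrs = feat.attributes
            tid = (attrs.get("transcript_id") or [None])[0]
            gid = (attrs.get("gene_id") or [None])[0]
            if tid is None or gid is None:
                raise ParseError(
                    f"{path}:{lineno}: exon lacks gene_id/transcript_id attributes"
                )
            raw_bt = None
            for key in (
                "gene_type",
                "gene_biotype",
                "transcript_type",
                "transcript_biotype",
                "biotype",
            ):
                if key in attrs:
                    raw_bt = attrs[key][0]
                    break
            try:
                iv = GenomicInterval(
                    feat.seqid, int(feat.start) - 1, int(feat.end), feat.strand
                )
            except (ValidationError, TypeError, ValueError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}")
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
                meta[tid] = (gid, normalize_biotype(raw_bt))
            exons[tid].append(iv)

    ann = Annotation(source_tag=source_tag)
    for tid in order:
        gid, biotype = meta[tid]
        try:
            ann.add(TranscriptModel(tid, gid, tuple(exons[tid]), biotype))
        except ValidationError as exc:
            raise ValidationError(f"{path}: transcript {tid}: {exc}")
    return ann


_BIOTYPE_OUT = {  # internal -> attribute value written back out
    "protein_coding": "protein_coding",
    "pseudogene": "pseudogene",
    "lncRNA": "lncRNA",
    "unknown": "unknown",
}


def write_gtf(
    transcripts: Iterable[TranscriptModel] | Annotation,
    path: str | Path,
    source: str = "lincpipe",
) -> None:
    """Write exon lines in GTF (1-based inclusive), deterministically ordered."""
    if isinstance(transcripts, Annotation):
        transcripts = list(transcripts.transcripts())
    ts = sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id))
    with Path(path).open("w") as fh:
        for t in ts:
            attr = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_type "{_BIOTYPE_OUT[t.biotype]}";'
            )
            for e in t.exons:
                fh.write(
                    "\t".join(
                        (
                            t.chrom,
                            source,
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            t.strand,
                            ".",
                            attr,
                        )
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ records as-is (BED is already 0-based half-open).

    Strand is taken from column 6 when present, otherwise ``.``.
    """
    path = Path(path)
    out: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = re.split(r"\s+", line.strip())
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer BED coordinates")
            strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}")
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    ivs = sorted(intervals)
    with Path(path).open("w") as fh:
        for iv in ivs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Expression tables


def read_expression_table(path: str | Path) -> dict[str, dict[str, float]]:
    """Read a TSV with header ``transcript_id<TAB><col>...`` into a nested map.

    Values must parse as non-negative floats; missing cells and duplicate
    transcript ids are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "transcript_id":
        raise ParseError(f"{path}: first column must be 'transcript_id'")
    if df["transcript_id"].duplicated().any():
        dup = df["transcript_id"][df["transcript_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate transcript_id {dup!r}")
    value_cols = list(df.columns[1:])
    values = df[value_cols].apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        raise ValidationError(f"{path}: missing or non-numeric expression values")
    if (values < 0).any().any():
        raise ValidationError(f"{path}: negative FPKM values")
    out: dict[str, dict[str, float]] = {}
    for tid, row in zip(df["transcript_id"], values.itertuples(index=False)):
        out[tid] = dict(zip(value_cols, (float(v) for v in row)))
    return out


def write_expression_table(
    table: Mapping[str, Mapping[str, float]], path: str | Path
) -> None:
    """Write the nested map back to TSV; column order follows the first record."""
    if not table:
        Path(path).write_text("transcript_id\n")
        return
    first = next(iter(table.values()))
    cols = list(first)
    df = pd.DataFrame(
        [[tid] + [vals[c] for c in cols] for tid, vals in table.items()],
        columns=["transcript_id"] + cols,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Locus strings

# accepts ASCII hyphen and the unicode hyphen that journal tables use
_LOCUS_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<a>\d+)[‐‑‒–-](?P<b>\d+)$")


def parse_locus(text: str, strand: str = ".") -> GenomicInterval:
    """Parse a browser-style ``chrN:A-B`` span (1-based inclusive) to internal."""
    m = _LOCUS_RE.match(text.strip())
    if not m:
        raise ParseError(f"cannot parse locus string {text!r}")
    return GenomicInterval(m["chrom"], int(m["a"]) - 1, int(m["b"]), strand)


def format_locus(iv: GenomicInterval) -> str:
    """Inverse of :func:`parse_locus` (1-based inclusive rendering)."""
    return f"{iv.chrom}:{iv.start + 1}-{iv.end}"
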