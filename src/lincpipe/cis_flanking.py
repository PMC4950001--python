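"""Nearest coding-gene pairing by TSS distance and the cis fold-change correlation.

A lincRNA is paired with the protein-coding gene (any strand, same
chromosome) whose strand-aware TSS is closest to the lincRNA's TSS;
there is no distance cap. A pair is "mRNA-flanking" when that distance
is strictly below the threshold (default 5 kb). The cis signal is the
Pearson correlation between the absolute log2 fold changes of flanking
lincRNAs and their nearest *expressed* coding genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

from lincpipe.genomic_io import Annotation, TranscriptModel

__all__ = [
    "FlankingPair",
    "CorrelationResult",
    "nearest_coding_tss",
    "flag_flanking",
    "fc_correlation",
]

FLANKING_THRESHOLD_BP = 5000


@dataclass
class FlankingPair:
    """A lincRNA paired with its nearest coding gene by TSS distance.

    ``gene_id is None`` encodes the explicit no-neighbor result (no
    coding gene on the chromosome). ``signed_distance_bp`` is positive
    when the gene TSS lies downstream of the lincRNA TSS in the
    lincRNA's orientation.
    """

    lincrna_id: str
    gene_id: str | None
    tss_distance_bp: int | None
    signed_distance_bp: int | None = None
    is_flanking: bool = False
    tie_gene_ids: tuple[str, ...] = ()
    linc_abs_fc: float | None = None
    gene_abs_fc: float | None = None

    @property
    def has_neighbor(self) -> bool:
        return self.gene_id is not None

    @property
    def tss_distance_kb(self) -> float | None:
        if self.tss_distance_bp is None:
            return None
        return round(self.tss_distance_bp / 1000.0, 3)


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    n_dropped: int = 0
    degenerate: bool = False


def _gene_tss_candidates(
    annotation: Annotation, chrom: str
) -> list[tuple[str, int]]:
    out = []
    for gid, transcripts in annotation.genes.items():
        for t in transcripts:
            if t.biotype == "protein_coding" and t.chrom == chrom:
                out.append((gid, t.tss))
    return out


def nearest_coding_tss(
    linc: TranscriptModel,
    annotation: Annotation,
    min_fpkm: float | None = None,
    flanking_threshold_bp: int = FLANKING_THRESHOLD_BP,
) -> FlankingPair:
    """Pair ``linc`` with the nearest protein-coding TSS on its chromosome.

    The distance is the minimum over coding transcripts (any strand) of
    |linc TSS - gene TSS|, both strand-aware 5' ends. With
    ``min_fpkm`` set, only genes whose transcripts reach that expression
    in some condition are eligible ("nearest expressed"). Distance ties
    across genes resolve to the lexicographically smaller gene_id, with
    all tied genes reported.
    """
    best: dict[str, tuple[int, int]] = {}  # gene_id -> (distance, signed)
    for gid, transcripts in annotation.genes.items():
        cand = [
            t
            for t in transcripts
            if t.biotype == "protein_coding" and t.chrom == linc.chrom
        ]
        if min_fpkm is not None:
            cand = [t for t in cand if t.max_fpkm >= min_fpkm]
        for t in cand:
            d = abs(t.tss - linc.tss)
            if gid not in best or d < best[gid][0]:
                offset = t.tss - linc.tss
                signed = -offset if linc.strand == "-" else offset
                best[gid] = (d, signed)
    if not best:
        return FlankingPair(linc.transcript_id, None, None)
    dmin = min(d for d, _ in best.values())
    tied = sorted(gid for gid, (d, _) in best.items() if d == dmin)
    gid = tied[0]
    pair = FlankingPair(
        lincrna_id=linc.transcript_id,
        gene_id=gid,
        tss_distance_bp=dmin,
        signed_distance_bp=best[gid][1],
        tie_gene_ids=tuple(tied) if len(tied) > 1 else (),
    )
    pair.is_flanking = flag_flanking(pair, flanking_threshold_bp)
    return pair


def flag_flanking(pair: FlankingPair, threshold_bp: int = FLANKING_THRESHOLD_BP) -> bool:
    """Strictly-below-threshold TSS distance (5,000 bp is *not* flanking)."""
    if pair.tss_distance_bp is None:
        raise ValueError(f"{pair.lincrna_id}: no neighbor, distance undefined")
    return pair.tss_distance_bp < threshold_bp


def fc_correlation(pairs: list[FlankingPair]) -> CorrelationResult:
    """Pearson r between |log2 FC| of lincRNAs and of their nearest genes.

    Pairs lacking a fold change on either side (e.g. gene not expressed)
    are dropped and counted. Zero variance in either vector yields an
    explicit degenerate result rather than an exception.
    """
    usable = [
        p for p in pairs if p.linc_abs_fc is not None and p.gene_abs_fc is not None
    ]
    n_dropped = len(pairs) - len(usable)
    if len(usable) < 3:
        raise ValueError("fc_correlation needs >= 3 complete pairs")
    x = [p.linc_abs_fc for p in usable]
    y = [p.gene_abs_fc for p in usable]
    if len(set(x)) == 1 or len(set(y)) == 1:
        return CorrelationResult(
            math.nan, math.nan, len(usable), n_dropped, degenerate=True
        )
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(usable), n_dropped)
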