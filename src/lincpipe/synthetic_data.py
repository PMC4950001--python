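"""Seeded generators for every input the pipeline consumes, with planted truth.

The generators emulate the statistical structure the analysis assumes:

* a toy one-chromosome annotation with protein-coding genes (4-20 exons)
  and pseudogenes, all placed without overlap and with generous spacing;
* assembled transfrags whose true positional class is guaranteed by
  construction (intergenic; opposite-strand gene-overlapping;
  pseudogene-overlapping), with lengths/exon counts echoing the ~1.2 kb
  / ~3.6-exon lncRNA profile, and a stated fraction copied into a
  synthetic catalog ("known");
* a fraction of lincRNAs deliberately placed back-to-back with a coding
  gene, TSS-to-TSS distance < 5 kb, emulating mRNA-flanking
  (bidirectional-promoter) lincRNAs;
* FPKM tables with 3 replicates per condition, log-normal baselines,
  planted stimulus-induced fold changes, and a planted correlation
  between flanking-pair absolute fold changes;
* qPCR Ct tables and a 17-analyte cytokine panel with planted knockdown
  fractions and responder analytes.

Every generator takes an explicit seed and is byte-deterministic given
it; seeds and parameters are recorded in the serialized truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from lincpipe.genomic_io import (
    Annotation,
    GenomicInterval,
    TranscriptModel,
    write_bed,
    write_expression_table,
    write_gtf,
)

__all__ = [
    "SyntheticTruth",
    "make_annotation",
    "make_transfrags",
    "make_enhancers",
    "make_expression",
    "make_assays",
    "sample_flanking_fc_estimates",
    "simulate_all",
]

_SPACING = 8000  # minimum gap between placed gene spans, bp
_MAX_TRIES = 2000


class PlacementError(RuntimeError):
    """Rejection sampling could not place a feature within the retry cap."""


@dataclass
class SyntheticTruth:
    """Ground truth for a synthetic dataset; serializes losslessly to JSON."""

    classes: dict[str, str] = field(default_factory=dict)
    novelty: dict[str, str] = field(default_factory=dict)
    de_status: dict[str, bool] = field(default_factory=dict)
    true_log2_fc: dict[str, float] = field(default_factory=dict)
    flanking_pairs: dict[str, str] = field(default_factory=dict)
    flanking_distance_bp: dict[str, int] = field(default_factory=dict)
    erna_ids: list[str] = field(default_factory=list)
    knockdown: dict[str, float] = field(default_factory=dict)
    responders: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with Path(path).open() as fh:
            return cls(**json.load(fh))


def _allocate(n: int, fracs: tuple[float, ...]) -> list[int]:
    """Largest-remainder integer allocation of ``n`` across ``fracs``."""
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    raw = [n * f for f in fracs]
    counts = [int(x) for x in raw]
    order = sorted(range(len(fracs)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[: n - sum(counts)]:
        counts[i] += 1
    return counts


class _Occupancy:
    """Span bookkeeping for rejection-sampled placement."""

    def __init__(self) -> None:
        self.tree = IntervalTree()

    def free(self, start: int, end: int, spacing: int = 0) -> bool:
        return not self.tree.overlap(start - spacing, end + spacing)

    def claim(self, start: int, end: int) -> None:
        self.tree.addi(start, end)


def _exon_chain(
    rng: np.random.Generator,
    chrom: str,
    strand: str,
    start: int,
    exon_lens: list[int],
    intron_lens: list[int],
) -> tuple[GenomicInterval, ...]:
    exons = []
    pos = start
    for i, length in enumerate(exon_lens):
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length
        if i < len(intron_lens):
            pos += intron_lens[i]
    return tuple(exons)


def _lnc_geometry(rng: np.random.Generator) -> tuple[list[int], list[int]]:
    """Exon/intron lengths echoing the short, few-exon lncRNA profile."""
    n_exons = int(min(1 + rng.poisson(2.6), 8))
    exon_lens = [int(rng.integers(200, 451)) for _ in range(n_exons)]
    intron_lens = [int(rng.integers(100, 801)) for _ in range(n_exons - 1)]
    return exon_lens, intron_lens


def make_annotation(
    n_coding: int = 30,
    n_pseudo: int = 10,
    chrom_length: int = 5_000_000,
    chrom: str = "chr1",
    seed: int = 0,
) -> Annotation:
    """Place coding genes and pseudogenes without overlap on one chromosome.

    Coding genes carry 4-20 exons (echoing the many-exon mRNA profile);
    pseudogenes 1-3. Spans keep a fixed safety gap so that flanking
    lincRNAs can later be planted between genes. Deterministic per seed.
    """
    if n_coding < 0 or n_pseudo < 0:
        raise ValueError("gene counts must be >= 0")
    rng = np.random.default_rng(seed)
    occ = _Occupancy()
    ann = Annotation(source_tag="synthetic_reference")
    specs = [("protein_coding", f"GENE{i:04d}") for i in range(n_coding)]
    specs += [("pseudogene", f"PSEUDO{i:04d}") for i in range(n_pseudo)]
    for biotype, gid in specs:
        if biotype == "protein_coding":
            n_exons = int(rng.integers(4, 21))
            exon_lens = [int(rng.integers(100, 301)) for _ in range(n_exons)]
            intron_lens = [int(rng.integers(200, 2001)) for _ in range(n_exons - 1)]
        else:
            n_exons = int(rng.integers(2, 5))
            exon_lens = [int(rng.integers(300, 801)) for _ in range(n_exons)]
            intron_lens = [int(rng.integers(500, 2501)) for _ in range(n_exons - 1)]
        span = sum(exon_lens) + sum(intron_lens)
        strand = str(rng.choice(["+", "-"]))
        for _ in range(_MAX_TRIES):
            start = int(rng.integers(0, chrom_length - span))
            if occ.free(start, start + span, _SPACING):
                occ.claim(start, start + span)
                exons = _exon_chain(rng, chrom, strand, start, exon_lens, intron_lens)
                ann.add(TranscriptModel(f"{gid}.1", gid, exons, biotype))
                break
        else:
            raise PlacementError(
                f"could not place {gid} on {chrom} of {chrom_length} bp"
            )
    return ann


def make_transfrags(
    annotation: Annotation,
    n: int = 200,
    class_mix: tuple[float, float, float] = (0.65, 0.13, 0.22),
    catalog_known_frac: float = 0.75,
    flanking_frac: float = 0.5,
    seed: int = 0,
) -> tuple[list[TranscriptModel], Annotation, SyntheticTruth]:
    """Generate transfrags realizing planted classes, plus a catalog and truth.

    ``class_mix`` gives the (lincRNA, antisense, pseudogene) fractions,
    allocated exactly by largest remainder. ``flanking_frac`` of the
    lincRNAs are placed back-to-back with a coding-gene TSS at a planted
    distance < 5 kb (each such gene hosts at most one flanking lincRNA).
    ``catalog_known_frac`` of transfrags are copied, exon-identical,
    into the synthetic catalog and are therefore "known".
    """
    rng = np.random.default_rng(seed)
    n_linc, n_anti, n_pseudo = _allocate(n, tuple(class_mix))
    chrom_lengths = {}
    occ = _Occupancy()
    coding, pseudo = [], []
    for t in annotation.transcripts():
        occ.claim(t.start, t.end)
        chrom_lengths[t.chrom] = max(chrom_lengths.get(t.chrom, 0), t.end + 50_000)
        (coding if t.biotype == "protein_coding" else pseudo).append(t)
    if not coding and (n_anti or n_linc):
        raise PlacementError("annotation has no coding genes")
    if not pseudo and n_pseudo:
        raise PlacementError("annotation has no pseudogenes")

    truth = SyntheticTruth(
        params={
            "seed": seed,
            "n": n,
            "class_mix": list(class_mix),
            "catalog_known_frac": catalog_known_frac,
            "flanking_frac": flanking_frac,
        }
    )
    transfrags: list[TranscriptModel] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"XLOC_{counter:05d}"

    # flanking lincRNAs: back-to-back with a coding TSS, distance < 5 kb
    n_flank = int(round(flanking_frac * n_linc))
    if n_flank > len(coding):
        raise PlacementError("not enough coding genes to host flanking lincRNAs")
    host_idx = rng.choice(len(coding), size=n_flank, replace=False)
    for gi in host_idx:
        g = coding[int(gi)]
        placed = False
        for _ in range(_MAX_TRIES):
            d = int(rng.integers(200, 4500))
            exon_lens, intron_lens = _lnc_geometry(rng)
            span = sum(exon_lens) + sum(intron_lens)
            if g.strand == "+":
                # lincRNA on '-' ending d bp upstream of the gene TSS
                end = g.start - d
                start = end - span
                strand = "-"
            else:
                start = g.end + d
                end = start + span
                strand = "+"
            if start < 0 or end > chrom_lengths[g.chrom]:
                continue
            if occ.free(start, end):
                tid = next_id()
                exons = _exon_chain(rng, g.chrom, strand, start, exon_lens, intron_lens)
                transfrags.append(TranscriptModel(tid, tid, exons, "unknown"))
                occ.claim(start, end)
                truth.classes[tid] = "lincRNA"
                truth.flanking_pairs[tid] = g.gene_id
                truth.flanking_distance_bp[tid] = d
                placed = True
                break
        if not placed:
            raise PlacementError(f"could not place flanking lincRNA near {g.gene_id}")

    # background (non-flanking) lincRNAs: anywhere gene- and transfrag-free
    chrom = coding[0].chrom if coding else pseudo[0].chrom
    limit = chrom_lengths[chrom]
    for _ in range(n_linc - n_flank):
        for _ in range(_MAX_TRIES):
            exon_lens, intron_lens = _lnc_geometry(rng)
            span = sum(exon_lens) + sum(intron_lens)
            start = int(rng.integers(0, limit - span))
            if occ.free(start, start + span):
                tid = next_id()
                strand = str(rng.choice(["+", "-"]))
                exons = _exon_chain(rng, chrom, strand, start, exon_lens, intron_lens)
                transfrags.append(TranscriptModel(tid, tid, exons, "unknown"))
                occ.claim(start, start + span)
                truth.classes[tid] = "lincRNA"
                break
        else:
            raise PlacementError("could not place intergenic lincRNA")

    # antisense / pseudogene-overlapping transfrags: >= 1 exon bp on the
    # host span; the transcript may extend beyond it but must stay clear
    # of every other gene and transfrag (classes and novelty stay exact)
    for lnc_class, hosts, count in (
        ("antisense", coding, n_anti),
        ("pseudogene", pseudo, n_pseudo),
    ):
        for _ in range(count):
            placed = False
            for _ in range(_MAX_TRIES):
                g = hosts[int(rng.integers(0, len(hosts)))]
                exon_lens, intron_lens = _lnc_geometry(rng)
                span = sum(exon_lens) + sum(intron_lens)
                lo = max(0, g.start - span + 100)
                start = int(rng.integers(lo, g.end - 100))
                if not _free_among_transfrags(occ, g, start, start + span):
                    continue
                if lnc_class == "antisense":
                    strand = "-" if g.strand == "+" else "+"
                else:
                    strand = str(rng.choice(["+", "-"]))
                tid = next_id()
                exons = _exon_chain(rng, g.chrom, strand, start, exon_lens, intron_lens)
                t = TranscriptModel(tid, tid, exons, "unknown")
                if not any(e.start < g.end and g.start < e.end for e in t.exons):
                    counter -= 1  # intron-only overlap: retry
                    continue
                transfrags.append(t)
                occ.claim(start, start + span)
                truth.classes[tid] = lnc_class
                placed = True
                break
            if not placed:
                raise PlacementError(f"could not place {lnc_class} transfrag")

    # catalog: exon-identical copies of a sampled fraction => "known"
    n_known = int(round(catalog_known_frac * len(transfrags)))
    known_idx = set(rng.choice(len(transfrags), size=n_known, replace=False).tolist())
    catalog = Annotation(source_tag="synthetic_catalog")
    for i, t in enumerate(transfrags):
        if i in known_idx:
            catalog.add(
                TranscriptModel(f"CAT_{t.transcript_id}", f"CATG_{t.transcript_id}",
                                t.exons, "lncRNA")
            )
            truth.novelty[t.transcript_id] = "known"
        else:
            truth.novelty[t.transcript_id] = "novel"
    return transfrags, catalog, truth


def _free_among_transfrags(occ: _Occupancy, host, start: int, end: int) -> bool:
    """Free except for the host gene's own span (transfrags must nest in it)."""
    hits = occ.tree.overlap(start, end)
    return all(iv.begin == host.start and iv.end == host.end for iv in hits)


def make_enhancers(
    annotation: Annotation,
    transfrags: list[TranscriptModel],
    truth: SyntheticTruth,
    overlap_frac: float = 0.03,
    n_background: int = 40,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Enhancer intervals overlapping a planted fraction of transfrags.

    Overlapping enhancers sit strictly inside the first exon of their
    target (so exactly the planted set is flagged); background enhancers
    avoid all transfrag spans. Flagged ids go to ``truth.erna_ids``.
    """
    rng = np.random.default_rng(seed)
    n_hit = int(round(overlap_frac * len(transfrags)))
    hit_idx = rng.choice(len(transfrags), size=n_hit, replace=False)
    out: list[GenomicInterval] = []
    flagged = []
    for i in sorted(int(j) for j in hit_idx):
        e = transfrags[i].exons[0]
        end = min(e.start + 150, e.end - 1)
        out.append(GenomicInterval(e.chrom, e.start + 1, end, "."))
        flagged.append(transfrags[i].transcript_id)
    spans = IntervalTree()
    limit = 0
    for t in transfrags:
        spans.addi(t.start, t.end)
        limit = max(limit, t.end + 50_000)
    for _ in range(n_background):
        for _ in range(_MAX_TRIES):
            start = int(rng.integers(0, limit - 400))
            if not spans.overlap(start, start + 300):
                out.append(GenomicInterval(transfrags[0].chrom, start, start + 300, "."))
                break
        else:
            raise PlacementError("could not place background enhancer")
    truth.erna_ids = sorted(flagged)
    return out


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float
) -> float:
    for _ in range(1000):
        x = float(rng.normal(mean, sd))
        if x >= lower:
            return x
    return lower


def make_expression(
    annotation: Annotation,
    transfrags: list[TranscriptModel],
    truth: SyntheticTruth,
    n_reps: int = 3,
    de_frac: float = 0.10,
    lfc_dist: tuple[float, float] = (3.0, 1.5),
    up_frac: float = 0.85,
    noise_sd: float = 0.25,
    cis_rho: float = 0.6,
    pair_lfc_dist: tuple[float, float] = (3.0, 1.5),
    mrna_de_frac: float = 0.10,
    baseline_floor_fpkm: float = 1.5,
    conditions: tuple[str, str] = ("control", "IL1b"),
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Generate a replicate FPKM table with planted effects; updates truth.

    Baselines are log-normal (lncRNA-level median ~4.7 FPKM, mRNA-level
    ~29.6), truncated at ``baseline_floor_fpkm`` — the generated
    universe emulates an already expression-filtered discovery set.
    Flanking pairs receive correlated absolute log2 fold changes
    (correlation ``cis_rho``); ``de_frac`` of the remaining transfrags
    receive a signed planted fold change; replicate noise is i.i.d.
    normal on the log2 scale.
    """
    if not (0 <= de_frac <= 1 and 0 <= cis_rho <= 1):
        raise ValueError("parameters out of range")
    rng = np.random.default_rng(seed)
    ctrl, stim = conditions
    floor_log2 = math.log2(baseline_floor_fpkm)

    lfc: dict[str, float] = {}
    # correlated planted effects for flanking pairs (lincRNA up, gene up)
    mean, sd = pair_lfc_dist
    cov = [[sd**2, cis_rho * sd**2], [cis_rho * sd**2, sd**2]]
    gene_tids = {
        gid: [t.transcript_id for t in ts] for gid, ts in annotation.genes.items()
    }
    for linc_tid in sorted(truth.flanking_pairs):
        gid = truth.flanking_pairs[linc_tid]
        a, b = np.abs(rng.multivariate_normal([mean, mean], cov))
        lfc[linc_tid] = float(a)
        for tid in gene_tids[gid]:
            lfc[tid] = float(b)

    # independent planted DE among the remaining transfrags
    rest = [t.transcript_id for t in transfrags if t.transcript_id not in lfc]
    n_de = int(round(de_frac * len(transfrags)))
    n_de = min(n_de, len(rest))
    de_ids = sorted(
        np.array(rest)[rng.choice(len(rest), size=n_de, replace=False)].tolist()
    ) if n_de else []
    for tid in de_ids:
        mag = abs(rng.normal(*lfc_dist))
        sign = 1.0 if rng.random() < up_frac else -1.0
        lfc[tid] = float(sign * mag)

    # planted DE among coding genes not already in a flanking pair
    coding_rest = [
        t.transcript_id
        for t in annotation.transcripts()
        if t.biotype == "protein_coding" and t.transcript_id not in lfc
    ]
    n_mde = int(round(mrna_de_frac * len(coding_rest)))
    for i in rng.choice(len(coding_rest), size=n_mde, replace=False) if n_mde else []:
        mag = abs(rng.normal(*lfc_dist))
        sign = 1.0 if rng.random() < up_frac else -1.0
        lfc[coding_rest[int(i)]] = float(sign * mag)

    table: dict[str, dict[str, float]] = {}
    all_models = list(transfrags) + list(annotation.transcripts())
    for t in all_models:
        if t.biotype == "protein_coding":
            base = _truncated_normal(rng, math.log2(29.6), 1.5, floor_log2)
        else:
            base = _truncated_normal(rng, math.log2(4.7), 1.5, floor_log2)
        effect = lfc.get(t.transcript_id, 0.0)
        row: dict[str, float] = {}
        for r in range(1, n_reps + 1):
            row[f"{ctrl}_{r}"] = float(2 ** (base + rng.normal(0, noise_sd)))
        for r in range(1, n_reps + 1):
            row[f"{stim}_{r}"] = float(2 ** (base + effect + rng.normal(0, noise_sd)))
        table[t.transcript_id] = row

    for t in transfrags:
        tid = t.transcript_id
        truth.true_log2_fc[tid] = lfc.get(tid, 0.0)
        truth.de_status[tid] = tid in lfc
    for t in annotation.transcripts():
        truth.true_log2_fc[t.transcript_id] = lfc.get(t.transcript_id, 0.0)
        truth.de_status[t.transcript_id] = t.transcript_id in lfc
    truth.params.update(
        {
            "expression_seed": seed,
            "n_reps": n_reps,
            "de_frac": de_frac,
            "lfc_dist": list(lfc_dist),
            "noise_sd": noise_sd,
            "cis_rho": cis_rho,
            "conditions": list(conditions),
        }
    )
    return table


def sample_flanking_fc_estimates(
    n_pairs: int,
    rho: float = 0.6,
    mean: float = 3.0,
    sd: float = 1.5,
    noise_sd: float = 0.25,
    n_reps: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted-correlation |log2 FC| pairs plus replicate estimation noise.

    The measured log2 FC of a transcript with ``n_reps`` replicates per
    condition and log-scale replicate noise ``noise_sd`` carries
    estimation noise with sd ``noise_sd * sqrt(2 / n_reps)``; this
    samples the estimates directly, matching what
    :func:`make_expression` plus the DE stage produce.
    """
    rng = np.random.default_rng(seed)
    cov = [[sd**2, rho * sd**2], [rho * sd**2, sd**2]]
    true = rng.multivariate_normal([mean, mean], cov, size=n_pairs)
    est_sd = noise_sd * math.sqrt(2.0 / n_reps)
    est = true + rng.normal(0.0, est_sd, size=true.shape)
    return np.abs(est[:, 0]), np.abs(est[:, 1])


def make_assays(
    knockdown: dict[str, float] | None = None,
    responders: tuple[str, ...] = ("IL-6", "IL-8", "TNF", "MIP-1b", "G-CSF"),
    responder_fold: float = 3.0,
    nd_analytes: tuple[str, ...] = ("IL-4", "IL-13"),
    stimulant: str = "IL-1b",
    kd_condition_of: str = "CILinc01",
    n_reps: int = 3,
    ct_noise_sd: float = 0.05,
    panel_log2_noise_sd: float = 0.15,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a qPCR Ct table and a 17-plex cytokine panel with planted truth.

    Default knockdown fractions (0.63 / 0.74) emulate the anti-CILinc01
    and anti-CILinc02 GapmeR efficiencies; with zero Ct noise the ddCt
    analysis recovers them exactly. Responder analytes get a
    ``responder_fold`` increase in the knockdown condition; ``nd_analytes``
    stay below the 1 pg/ml detection floor; the stimulant analyte is
    present at a high, condition-independent level (to be discounted).
    """
    from lincpipe.assay_stats import PANEL_17

    if knockdown is None:
        knockdown = {"CILinc01": 0.63, "CILinc02": 0.74}
    for target, k in knockdown.items():
        if not (0 <= k < 1):
            raise ValueError(f"knockdown fraction for {target!r} must be in [0, 1)")
    rng = np.random.default_rng(seed)

    ct_rows = []
    for target in sorted(knockdown):
        k = knockdown[target]
        d0 = 12.0  # baseline dCt target-vs-18S
        for cond, shift in (("NTC", 0.0), (f"anti-{target}", -math.log2(1.0 - k))):
            for i in range(1, n_reps + 1):
                ct_ref = 10.0 + float(rng.normal(0, ct_noise_sd))
                ct_t = ct_ref + d0 + shift + float(rng.normal(0, ct_noise_sd))
                ct_rows.append(
                    {
                        "sample_id": f"{target}_{cond}_{i}",
                        "condition": cond,
                        "target": target,
                        "ct_target": ct_t,
                        "ct_reference": ct_ref,
                    }
                )
    ct_df = pd.DataFrame(ct_rows)

    panel_rows = []
    kd_cond = f"anti-{kd_condition_of}"
    baselines = {a: float(rng.uniform(20, 200)) for a in PANEL_17}
    for a in nd_analytes:
        baselines[a] = 0.4
    baselines[stimulant] = 900.0
    for analyte in PANEL_17:
        for cond in ("NTC", kd_cond):
            level = baselines[analyte]
            if cond == kd_cond and analyte in responders:
                level *= responder_fold
            for i in range(1, n_reps + 1):
                value = level * 2 ** float(rng.normal(0, panel_log2_noise_sd))
                panel_rows.append(
                    {
                        "sample_id": f"{cond}_{i}",
                        "condition": cond,
                        "analyte": analyte,
                        "concentration": value,
                    }
                )
    panel_df = pd.DataFrame(panel_rows)
    if truth is not None:
        truth.knockdown = dict(knockdown)
        truth.responders = sorted(responders)
        truth.params.update({"assay_seed": seed, "responder_fold": responder_fold})
    return ct_df, panel_df


def simulate_all(
    outdir: str | Path,
    seed: int = 17,
    n_coding: int = 80,
    n_pseudo: int = 25,
    chrom_length: int = 12_000_000,
    n_transfrags: int = 200,
    class_mix: tuple[float, float, float] = (0.65, 0.13, 0.22),
    catalog_known_frac: float = 0.75,
    flanking_frac: float = 0.5,
    de_frac: float = 0.10,
    lfc_dist: tuple[float, float] = (3.0, 1.5),
    noise_sd: float = 0.25,
    cis_rho: float = 0.6,
) -> dict[str, Path]:
    """Write one complete synthetic dataset (all pipeline inputs + truth.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann = make_annotation(n_coding, n_pseudo, chrom_length, seed=seed)
    transfrags, catalog, truth = make_transfrags(
        ann,
        n=n_transfrags,
        class_mix=class_mix,
        catalog_known_frac=catalog_known_frac,
        flanking_frac=flanking_frac,
        seed=seed + 1,
    )
    enhancers = make_enhancers(ann, transfrags, truth, seed=seed + 2)
    table = make_expression(
        ann,
        transfrags,
        truth,
        de_frac=de_frac,
        lfc_dist=lfc_dist,
        noise_sd=noise_sd,
        cis_rho=cis_rho,
        seed=seed + 3,
    )
    ct_df, panel_df = make_assays(seed=seed + 4, truth=truth)

    paths = {
        "annotation": outdir / "annotation.gtf",
        "transfrags": outdir / "transfrags.gtf",
        "catalog": outdir / "catalog.gtf",
        "enhancers": outdir / "enhancers.bed",
        "expression": outdir / "expression.tsv",
        "ct": outdir / "ct.csv",
        "panel": outdir / "panel.csv",
        "truth": outdir / "truth.json",
    }
    write_gtf(ann, paths["annotation"])
    write_gtf(transfrags, paths["transfrags"])
    write_gtf(catalog, paths["catalog"])
    write_bed(enhancers, paths["enhancers"])
    write_expression_table(table, paths["expression"])
    ct_df.to_csv(paths["ct"], index=False)
    panel_df.to_csv(paths["panel"], index=False)
    truth.params["simulate_seed"] = seed
    truth.to_json(paths["truth"])
    return paths
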