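"""End-to-end orchestration: discovery -> classification -> DE -> cis -> report.

One configured run consumes a transfrag GTF, a reference annotation GTF,
optional catalog GTFs and an enhancer BED, plus a replicate FPKM table,
and writes deterministic stage outputs under
``outdir/{discovery,classify,diffexp,cis,report}/``. Identical config and
inputs produce byte-identical outputs (no timestamps in result files).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lincpipe import classify as _classify
from lincpipe import diffexp as _diffexp
from lincpipe.cis_flanking import fc_correlation, nearest_coding_tss
from lincpipe.discovery import DiscoveryConfig, filter_transfrags, summarize_features
from lincpipe.genomic_io import (
    Annotation,
    read_bed,
    read_expression_table,
    read_gtf,
    write_gtf,
)

__all__ = ["RunConfig", "PipelineError", "run_all", "validate_inputs"]

logger = logging.getLogger("lincpipe")

CONFIG_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All thresholds and paths of one pipeline run; YAML round-trips."""

    transfrags_gtf: str
    annotation_gtf: str
    expression_tsv: str
    catalogs: dict[str, str] = field(default_factory=dict)
    enhancers_bed: str | None = None
    ctrl_condition: str = "control"
    stim_condition: str = "IL1b"
    # discovery
    min_fpkm: float = 1.0
    min_length: int = 200
    min_exons: int = 1
    # classification
    min_recip_overlap: float = 0.5
    antisense_mode: str = "span"
    # differential expression
    fdr_max: float = 0.05
    min_fold: float = 2.0
    min_delta_fpkm: float = 1.0
    pseudocount: float = 0.1
    lnc_criterion: str = "p"
    mrna_criterion: str = "q"
    # cis / flanking
    flanking_threshold_bp: int = 5000
    nearest_min_fpkm: float = 1.0
    outdir: str = "lincpipe_out"
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["config_schema_version"] = CONFIG_SCHEMA_VERSION
        with Path(path).open("w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with path.open() as fh:
            data = yaml.safe_load(fh)
        data.pop("config_schema_version", None)
        cfg = cls(**data)
        # relative paths resolve against the YAML's directory
        base = path.parent
        for attr in ("transfrags_gtf", "annotation_gtf", "expression_tsv",
                     "enhancers_bed"):
            v = getattr(cfg, attr)
            if v is not None and not Path(v).is_absolute():
                setattr(cfg, attr, str(base / v))
        cfg.catalogs = {
            tag: (p if Path(p).is_absolute() else str(base / p))
            for tag, p in cfg.catalogs.items()
        }
        return cfg


def _attach_fpkm(models, table, conditions) -> None:
    """Set per-condition mean FPKM on transcript models from replicate columns."""
    for t in models:
        row = table.get(t.transcript_id)
        if row is None:
            continue
        t.fpkm = {
            cond: float(np.mean([v for k, v in row.items() if k.startswith(cond + "_")]))
            for cond in conditions
        }


def validate_inputs(config: RunConfig) -> list[str]:
    """Consistency checks across inputs; an empty list means runnable.

    Reports (never raises): missing files, chromosome naming style
    mismatches between GTF and BED, expression-table ids absent from the
    GTFs, and missing replicate columns for the configured conditions.
    """
    issues: list[str] = []
    paths = {
        "transfrags_gtf": config.transfrags_gtf,
        "annotation_gtf": config.annotation_gtf,
        "expression_tsv": config.expression_tsv,
        **{f"catalog:{tag}": p for tag, p in config.catalogs.items()},
    }
    if config.enhancers_bed:
        paths["enhancers_bed"] = config.enhancers_bed
    for label, p in paths.items():
        if not Path(p).exists():
            issues.append(f"{label}: file not found: {p}")
    if issues:
        return issues
    try:
        ann = read_gtf(config.annotation_gtf)
        tf = read_gtf(config.transfrags_gtf)
        table = read_expression_table(config.expression_tsv)
    except Exception as exc:
        return issues + [f"parse failure: {exc}"]
    known_ids = {t.transcript_id for t in tf.transcripts()} | {
        t.transcript_id for t in ann.transcripts()
    }
    orphans = sorted(set(table) - known_ids)
    if orphans:
        issues.append(
            f"expression table ids absent from GTFs: {', '.join(orphans[:5])}"
            + (" ..." if len(orphans) > 5 else "")
        )
    gtf_styles = {c.startswith("chr") for c in ann.chroms() | tf.chroms()}
    if len(gtf_styles) > 1:
        issues.append("mixed chromosome naming styles within GTF inputs")
    if config.enhancers_bed:
        bed_chroms = {iv.chrom for iv in read_bed(config.enhancers_bed)}
        bed_styles = {c.startswith("chr") for c in bed_chroms}
        if bed_styles and gtf_styles and bed_styles != gtf_styles:
            issues.append(
                "chromosome naming style differs between BED and GTF "
                "(e.g. '6' vs 'chr6')"
            )
    if table:
        cols = set(next(iter(table.values())))
        for cond in (config.ctrl_condition, config.stim_condition):
            if not any(c.startswith(cond + "_") for c in cols):
                issues.append(f"no replicate columns for condition {cond!r}")
    return issues


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run report."""
    out = Path(config.outdir)
    for sub in ("discovery", "classify", "diffexp", "cis", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        annotation = read_gtf(config.annotation_gtf, source_tag="reference")
        transfrags = list(read_gtf(config.transfrags_gtf, "transfrags").transcripts())
        catalogs = {tag: read_gtf(p, tag) for tag, p in config.catalogs.items()}
        enhancers = read_bed(config.enhancers_bed) if config.enhancers_bed else []
        table = read_expression_table(config.expression_tsv)
        conditions = (config.ctrl_condition, config.stim_condition)
        _attach_fpkm(transfrags, table, conditions)
        _attach_fpkm(list(annotation.transcripts()), table, conditions)

        stage = "discovery"
        dcfg = DiscoveryConfig(config.min_fpkm, config.min_length, config.min_exons)
        kept, rejected = filter_transfrags(transfrags, annotation, dcfg)
        write_gtf(kept, out / "discovery" / "kept.gtf")
        write_gtf([t for t, _ in rejected], out / "discovery" / "rejected.gtf")
        pd.DataFrame(
            [(t.transcript_id, reason) for t, reason in rejected],
            columns=["transcript_id", "reason"],
        ).sort_values("transcript_id").to_csv(
            out / "discovery" / "rejected_reasons.tsv", sep="\t", index=False
        )

        stage = "classify"
        classified = _classify.classify_all(
            kept,
            annotation,
            catalogs or None,
            enhancers,
            config.min_recip_overlap,
            config.antisense_mode,
        )
        cls_df = pd.DataFrame(
            [
                {
                    "transcript_id": c.transcript.transcript_id,
                    "class": c.lnc_class,
                    "novelty": c.novelty,
                    "matched_catalogs": ",".join(sorted(c.matched_catalogs)),
                    "erna_flag": c.erna_overlap,
                }
                for c in classified
            ]
        ).sort_values("transcript_id")
        cls_df.to_csv(out / "classify" / "classification.tsv", sep="\t", index=False)
        breakdown = _classify.class_breakdown(classified) if classified else {}
        erna_fraction = (
            float(np.mean([c.erna_overlap for c in classified])) if classified else 0.0
        )

        stage = "diffexp"
        kept_ids = sorted(
            t.transcript_id for t in kept if t.transcript_id in table
        )
        lnc_results = _diffexp.analyze_table(
            table, *conditions, config.pseudocount, kept_ids
        )
        _diffexp.call_differential(
            lnc_results,
            config.fdr_max,
            config.min_fold,
            config.min_delta_fpkm,
            config.lnc_criterion,
        )
        coding_ids = sorted(
            t.transcript_id
            for t in annotation.transcripts()
            if t.biotype == "protein_coding" and t.transcript_id in table
        )
        mrna_results = _diffexp.analyze_table(
            table, *conditions, config.pseudocount, coding_ids
        )
        _diffexp.call_differential(
            mrna_results,
            config.fdr_max,
            config.min_fold,
            config.min_delta_fpkm,
            config.mrna_criterion,
        )
        for name, results in (("lncrna_de", lnc_results), ("mrna_de", mrna_results)):
            pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
                out / "diffexp" / f"{name}.tsv", sep="\t", index=False
            )

        stage = "cis"
        by_tid = {c.transcript.transcript_id: c for c in classified}
        de_lincs = [
            r
            for r in lnc_results
            if r.call != "ns" and by_tid[r.transcript_id].lnc_class == "lincRNA"
        ]
        gene_abs_fc = {}
        for r in mrna_results:
            gid = annotation[r.transcript_id].gene_id
            gene_abs_fc.setdefault(gid, abs(r.log2_fc))
        pairs = []
        for r in de_lincs:
            pair = nearest_coding_tss(
                by_tid[r.transcript_id].transcript,
                annotation,
                min_fpkm=config.nearest_min_fpkm,
                flanking_threshold_bp=config.flanking_threshold_bp,
            )
            if pair.has_neighbor:
                pair.linc_abs_fc = abs(r.log2_fc)
                pair.gene_abs_fc = gene_abs_fc.get(pair.gene_id)
            pairs.append(pair)
        pd.DataFrame(
            [
                {
                    "lincrna_id": p.lincrna_id,
                    "gene_id": p.gene_id,
                    "tss_distance_bp": p.tss_distance_bp,
                    "tss_distance_kb": p.tss_distance_kb,
                    "is_flanking": p.is_flanking,
                    "linc_abs_fc": p.linc_abs_fc,
                    "gene_abs_fc": p.gene_abs_fc,
                }
                for p in sorted(pairs, key=lambda p: p.lincrna_id)
            ]
        ).to_csv(out / "cis" / "flanking_pairs.tsv", sep="\t", index=False)
        flanking = [p for p in pairs if p.has_neighbor and p.is_flanking]
        cis_summary: dict = {"n_pairs": len(pairs), "n_flanking": len(flanking)}
        complete = [
            p for p in flanking if p.linc_abs_fc is not None and p.gene_abs_fc is not None
        ]
        if len(complete) >= 3:
            corr = fc_correlation(complete)
            cis_summary.update(
                r=corr.r, p_value=corr.p_value, n=corr.n, degenerate=corr.degenerate
            )

        stage = "report"
        lnc_summary = summarize_features(kept) if kept else None
        report = {
            "config": dataclasses.asdict(config),
            "n_transfrags_in": len(transfrags),
            "n_lncrnas": len(kept),
            "n_rejected": len(rejected),
            "class_breakdown": breakdown,
            "erna_fraction": erna_fraction,
            "lncrna_features": dataclasses.asdict(lnc_summary) if lnc_summary else None,
            "de_lncrna": {
                "tested": len(lnc_results),
                "up": sum(r.call == "up" for r in lnc_results),
                "down": sum(r.call == "down" for r in lnc_results),
                "criterion": config.lnc_criterion,
            },
            "de_mrna": {
                "tested": len(mrna_results),
                "up": sum(r.call == "up" for r in mrna_results),
                "down": sum(r.call == "down" for r in mrna_results),
                "criterion": config.mrna_criterion,
            },
            "cis": cis_summary,
        }
        with (out / "report" / "report.json").open("w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        logger.info("run complete: %d lncRNAs, report at %s", len(kept), out)
        return report
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
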