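"""Two-condition differential expression on FPKM tables, plus pathway ORA.

The test is a two-sample t on log2(FPKM + pseudocount) per transcript — a
documented stand-in for count-model tests, reproducible from FPKM tables
alone. By default the pooled-variance (Student) form is used: with three
replicates per group it holds its nominal type-I error exactly under the
equal-variance null and coincides with the two-group one-way ANOVA used
for the wet-lab assays, whereas Welch's form is markedly conservative at
n = 3 (its Satterthwaite degrees of freedom are estimated from two
near-noise variances). Welch remains available via ``equal_var=False``.
The calling criteria carry the biology: a transcript is called
up/down only when (criterion statistic < fdr_max) AND (linear fold
change > min_fold) AND (|mean difference in FPKM| > min_delta_fpkm), all
strict inequalities.

Multiple testing uses Benjamini-Hochberg (statsmodels); pathway
over-representation uses the one-sided hypergeometric tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEResult",
    "EnrichmentResult",
    "de_test",
    "bh_adjust",
    "call_differential",
    "analyze_table",
    "pathway_enrichment",
    "read_gmt",
]

DEFAULT_PSEUDOCOUNT = 0.1


@dataclass
class DEResult:
    transcript_id: str
    mean_fpkm_ctrl: float
    mean_fpkm_stim: float
    log2_fc: float
    delta_fpkm: float
    p_value: float
    q_value: float = math.nan
    call: str = "ns"


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    overlap_count: int
    pathway_size: int
    set_size: int
    background_size: int
    p_value: float
    q_value: float = math.nan


def de_test(
    fpkm_ctrl: Sequence[float],
    fpkm_stim: Sequence[float],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    equal_var: bool = True,
) -> tuple[float, float, float]:
    """Two-sample t on log2(FPKM + pseudocount); returns (log2_fc, delta_fpkm, p).

    log2_fc = log2((mean_stim + pc) / (mean_ctrl + pc)). Groups with zero
    variance are handled explicitly: identical groups give p = 1; equal
    constants that differ give p = 0 (infinite evidence at this model).
    """
    ctrl = np.asarray(fpkm_ctrl, dtype=float)
    stim = np.asarray(fpkm_stim, dtype=float)
    if ctrl.size < 2 or stim.size < 2:
        raise ValueError("de_test needs >= 2 replicates per group")
    if (ctrl < 0).any() or (stim < 0).any():
        raise ValueError("negative FPKM")
    mean_c, mean_s = float(ctrl.mean()), float(stim.mean())
    log2_fc = math.log2((mean_s + pseudocount) / (mean_c + pseudocount))
    delta = abs(mean_s - mean_c)
    x = np.log2(ctrl + pseudocount)
    y = np.log2(stim + pseudocount)
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        p = 1.0 if x.mean() == y.mean() else 0.0
    else:
        p = float(stats.ttest_ind(y, x, equal_var=equal_var).pvalue)
    return log2_fc, delta, p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    results: list[DEResult],
    fdr_max: float = 0.05,
    min_fold: float = 2.0,
    min_delta_fpkm: float = 1.0,
    criterion: str = "q",
) -> list[DEResult]:
    """Label each result up/down/ns and return the called (non-ns) subset.

    ``criterion`` selects the significance statistic: ``"q"`` (FDR, as in
    the mRNA analysis) or ``"p"`` (raw p, as used for the lncRNA set).
    """
    if criterion not in ("q", "p"):
        raise ValueError("criterion must be 'q' or 'p'")
    min_abs_lfc = math.log2(min_fold)
    called: list[DEResult] = []
    for r in results:
        stat = r.q_value if criterion == "q" else r.p_value
        passes = (
            stat < fdr_max
            and abs(r.log2_fc) > min_abs_lfc
            and r.delta_fpkm > min_delta_fpkm
        )
        r.call = ("up" if r.log2_fc > 0 else "down") if passes else "ns"
        if r.call != "ns":
            called.append(r)
    return called


def analyze_table(
    table: Mapping[str, Mapping[str, float]],
    ctrl_condition: str,
    stim_condition: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    transcript_ids: Sequence[str] | None = None,
) -> list[DEResult]:
    """Run :func:`de_test` for each transcript of an expression table.

    Replicate columns are named ``<condition>_<rep>``. q-values are BH
    over the analyzed set, in input order.
    """
    ids = list(transcript_ids) if transcript_ids is not None else list(table)
    results: list[DEResult] = []
    for tid in ids:
        row = table[tid]
        ctrl = [v for k, v in row.items() if k.startswith(ctrl_condition + "_")]
        stim = [v for k, v in row.items() if k.startswith(stim_condition + "_")]
        if not ctrl or not stim:
            raise ValueError(
                f"{tid}: no replicate columns for "
                f"{ctrl_condition!r}/{stim_condition!r}"
            )
        lfc, delta, p = de_test(ctrl, stim, pseudocount)
        results.append(
            DEResult(
                transcript_id=tid,
                mean_fpkm_ctrl=float(np.mean(ctrl)),
                mean_fpkm_stim=float(np.mean(stim)),
                log2_fc=lfc,
                delta_fpkm=delta,
                p_value=p,
            )
        )
    if results:
        q = bh_adjust([r.p_value for r in results])
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    return results


def pathway_enrichment(
    de_genes: set[str],
    pathways: Mapping[str, set[str]],
    background: set[str],
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation per pathway, BH-adjusted.

    Pathways are intersected with the background first; pathways disjoint
    from it are excluded from testing. Results are sorted by (q, p, id).
    """
    if not background:
        raise ValueError("empty background")
    if not de_genes <= background:
        raise ValueError("de_genes must be a subset of background")
    m = len(background)
    n_set = len(de_genes)
    rows: list[EnrichmentResult] = []
    for pid in sorted(pathways):
        pw = pathways[pid] & background
        if not pw:
            continue
        k = len(pw & de_genes)
        # P(X >= k) drawing n_set from m with len(pw) successes
        p = float(stats.hypergeom.sf(k - 1, m, len(pw), n_set))
        rows.append(EnrichmentResult(pid, k, len(pw), n_set, m, p))
    if not rows:
        return []
    q = bh_adjust([r.p_value for r in rows])
    rows = [
        EnrichmentResult(
            r.pathway_id,
            r.overlap_count,
            r.pathway_size,
            r.set_size,
            r.background_size,
            r.p_value,
            float(qv),
        )
        for r, qv in zip(rows, q)
    ]
    return sorted(rows, key=lambda r: (r.q_value, r.p_value, r.pathway_id))


def read_gmt(path) -> dict[str, set[str]]:
    """Read GMT gene sets: name<TAB>description<TAB>gene1<TAB>gene2..."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            out[fields[0]] = set(g for g in fields[2:] if g)
    return out
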