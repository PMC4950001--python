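"""Wet-lab statistics: 2^-ddCt quantification, ANOVA + Fisher's LSD,
knockdown percentages, and multiplex cytokine panel screening.

Relative qPCR quantification uses the classical ddCt method with
amplification efficiency fixed at 2: dCt = Ct(target) - Ct(reference),
ddCt = dCt(sample) - mean dCt(calibrator group), RQ = 2^-ddCt. Because
the calibrator centering happens on the log (Ct) scale, the *geometric*
mean RQ of the calibrator group is exactly 1.

Group comparisons follow the ANOVA-then-LSD convention: one-way ANOVA,
and pairwise Fisher least-significant-difference t-tests on the pooled
within-group mean square, reported (by default) only when the omnibus
test is significant at alpha.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PANEL_17",
    "AnovaLSDResult",
    "ddct_relative_expression",
    "anova_lsd",
    "knockdown_percent",
    "panel_screen",
]

#: the 17-plex proinflammatory panel measured in chondrocyte supernatants
PANEL_17 = (
    "IL-1b",
    "IL-2",
    "IL-4",
    "IL-5",
    "IL-6",
    "IL-7",
    "IL-8",
    "IL-10",
    "IL-12(p70)",
    "IL-13",
    "IL-17",
    "G-CSF",
    "GM-CSF",
    "IFN-g",
    "MCP-1",
    "MIP-1b",
    "TNF",
)

PANEL_FLOOR_PG_ML = 1.0
PANEL_CEILING_PG_ML = 2500.0


def ddct_relative_expression(
    records: pd.DataFrame, calibrator_condition: str
) -> pd.DataFrame:
    """Compute per-sample relative quantities by the ddCt method.

    ``records`` is long-format with columns ``sample_id, condition,
    target, ct_target, ct_reference`` (reference = 18S). Returns a copy
    with ``delta_ct``, ``delta_delta_ct`` and ``rq`` columns; the
    calibrator mean dCt is computed per target.
    """
    required = {"sample_id", "condition", "target", "ct_target", "ct_reference"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    df = records.copy()
    for col in ("ct_target", "ct_reference"):
        bad = df[df[col].isna() | ~np.isfinite(df[col]) | (df[col] <= 0)]
        if len(bad):
            raise ValueError(
                f"missing/invalid {col} for sample {bad['sample_id'].iloc[0]!r}"
            )
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    out = []
    for target, grp in df.groupby("target", sort=False):
        calib = grp.loc[grp["condition"] == calibrator_condition, "delta_ct"]
        if calib.empty:
            raise ValueError(
                f"target {target!r}: calibrator condition "
                f"{calibrator_condition!r} absent"
            )
        g = grp.copy()
        g["delta_delta_ct"] = g["delta_ct"] - calib.mean()
        g["rq"] = np.exp2(-g["delta_delta_ct"])
        out.append(g)
    return pd.concat(out, ignore_index=True)


@dataclass
class AnovaLSDResult:
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    ms_within: float
    group_means: dict[str, float]
    group_sizes: dict[str, int]
    #: pairwise LSD p-values, or None when suppressed by the protected rule
    pairwise: dict[tuple[str, str], float] | None = None


def anova_lsd(
    groups: Mapping[str, Sequence[float]],
    protected: bool = True,
    alpha: float = 0.05,
) -> AnovaLSDResult:
    """One-way ANOVA with Fisher's LSD post hoc comparisons.

    LSD pairwise tests use the pooled within-group mean square and its
    degrees of freedom, uncorrected for multiplicity; with
    ``protected=True`` (the default) they are reported only when the
    omnibus p < alpha.
    """
    if len(groups) < 2:
        raise ValueError("anova_lsd needs >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {k!r} has n < 2")
    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    k = len(arrays)
    n_total = all_vals.size
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_b, df_w = k - 1, n_total - k
    ms_w = ss_within / df_w
    if ss_within == 0.0:
        if ss_between == 0.0:
            f, p = 0.0, 1.0
        else:
            f, p = math.inf, 0.0
    else:
        f = (ss_between / df_b) / ms_w
        p = float(stats.f.sf(f, df_b, df_w))
    res = AnovaLSDResult(
        f_stat=float(f),
        p_value=p,
        df_between=df_b,
        df_within=df_w,
        ms_within=float(ms_w),
        group_means={k: float(a.mean()) for k, a in arrays.items()},
        group_sizes={k: int(a.size) for k, a in arrays.items()},
    )
    if protected and p >= alpha:
        return res
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in combinations(arrays, 2):
        xa, xb = arrays[a], arrays[b]
        se = math.sqrt(ms_w * (1 / xa.size + 1 / xb.size)) if ms_w > 0 else 0.0
        if se == 0.0:
            pw = 1.0 if xa.mean() == xb.mean() else 0.0
        else:
            t = (xa.mean() - xb.mean()) / se
            pw = float(2 * stats.t.sf(abs(t), df_w))
        pairwise[(a, b)] = pw
    res.pairwise = pairwise
    return res


def knockdown_percent(
    expr_control_lna: float, expr_targeting_lna: float
) -> float:
    """Percent reduction relative to the non-targeting control.

    100 * (1 - targeting/control); a targeting value above the control
    (no knockdown) is clamped to 0.
    """
    if expr_control_lna <= 0:
        raise ValueError("control expression must be > 0")
    if expr_targeting_lna < 0:
        raise ValueError("targeting expression must be >= 0")
    pct = 100.0 * (1.0 - expr_targeting_lna / expr_control_lna)
    return max(pct, 0.0)


def panel_screen(
    panel: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    floor: float = PANEL_FLOOR_PG_ML,
    ceiling: float = PANEL_CEILING_PG_ML,
    exclude_analytes: Sequence[str] = (),
    alpha: float = 0.05,
    min_fold: float = 2.0,
    known_analytes: Sequence[str] = PANEL_17,
) -> pd.DataFrame:
    """Screen a multiplex cytokine panel between two conditions.

    ``panel`` is long-format with columns ``sample_id, condition,
    analyte, concentration`` (pg/ml). Analytes with every value below
    ``floor`` are flagged not-detectable and excluded from testing;
    values above ``ceiling`` are flagged and winsorized to the ceiling
    for testing. The stimulant analyte can be excluded via
    ``exclude_analytes``. A responder is an analyte with omnibus
    p < alpha *and* fold change >= ``min_fold`` in either direction.
    """
    required = {"sample_id", "condition", "analyte", "concentration"}
    if required - set(panel.columns):
        raise ValueError(f"panel lacks columns: {sorted(required - set(panel.columns))}")
    for cond in (condition_a, condition_b):
        if cond not in set(panel["condition"]):
            raise ValueError(f"condition {cond!r} absent from panel")
    unknown = set(panel["analyte"]) - set(known_analytes)
    if unknown:
        warnings.warn(f"unknown analytes processed anyway: {sorted(unknown)}")
    rows = []
    for analyte, grp in panel.groupby("analyte", sort=True):
        a = grp.loc[grp["condition"] == condition_a, "concentration"].to_numpy(float)
        b = grp.loc[grp["condition"] == condition_b, "concentration"].to_numpy(float)
        n_over = int((a > ceiling).sum() + (b > ceiling).sum())
        a = np.minimum(a, ceiling)
        b = np.minimum(b, ceiling)
        excluded = analyte in exclude_analytes
        detectable = bool((np.concatenate([a, b]) >= floor).any())
        row = {
            "analyte": analyte,
            "detectable": detectable,
            "excluded": excluded,
            "n_out_of_range": n_over,
            "mean_a": float(a.mean()) if a.size else math.nan,
            "mean_b": float(b.mean()) if b.size else math.nan,
            "fold_change": math.nan,
            "p_value": math.nan,
            "responder": False,
        }
        if detectable and not excluded and a.size >= 2 and b.size >= 2:
            fold = row["mean_b"] / row["mean_a"] if row["mean_a"] > 0 else math.inf
            res = anova_lsd({condition_a: a, condition_b: b}, protected=False)
            row["fold_change"] = float(fold)
            row["p_value"] = res.p_value
            effect = max(fold, 1 / fold) if fold > 0 else math.inf
            row["responder"] = bool(res.p_value < alpha and effect >= min_fold)
        rows.append(row)
    return pd.DataFrame(rows).set_index("analyte")
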