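"""Comparative layer: group summaries and shape-safety correlations.

Summarises shape descriptors per functional group (mean +/- sample SD)
and correlates safety factors under base and tip biting against the
four shape ratios (bottom/top keratin thickness, depth, width, all
relative to beak length), with Bonferroni control at m = 4 per bite
mode, mirroring the reference analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["group_summary", "pearson", "bonferroni_flags",
           "shape_safety_correlations", "GROUP_ORDER", "SHAPE_FIELDS"]

GROUP_ORDER = ["crush", "probe_and_base", "probe", "tip"]
SHAPE_FIELDS = ["ker_bottom_ratio", "ker_top_ratio", "depth_ratio",
                "width_ratio"]


def group_summary(table: pd.DataFrame, fields=None) -> pd.DataFrame:
    """Per-group mean, sample SD (n-1) and N of shape descriptors.

    Groups are ordered crush, probe_and_base, probe, tip.  A group with
    a single member gets NaN for its SD (undefined).
    """
    fields = list(fields) if fields is not None else SHAPE_FIELDS
    if table["group"].isna().any():
        raise ValueError("every row must carry a functional group")
    unknown = set(table["group"]) - set(GROUP_ORDER)
    if unknown:
        raise ValueError(f"unknown groups {sorted(unknown)}")
    out = []
    for group in GROUP_ORDER:
        rows = table[table["group"] == group]
        if rows.empty:
            continue
        rec = {"group": group, "n": len(rows)}
        for f in fields:
            rec[f"{f}_mean"] = rows[f].mean()
            rec[f"{f}_sd"] = rows[f].std(ddof=1) if len(rows) > 1 else np.nan
        out.append(rec)
    return pd.DataFrame(out)


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided exact-t p-value.

    p comes from t = r sqrt((n-2)/(1-r^2)) referred to a t distribution
    with n-2 degrees of freedom; no asymptotics (sample sizes here are
    at most 13).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined correlation")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bonferroni_flags(pvals, alpha: float = 0.05, m: int | None = None
                     ) -> np.ndarray:
    """Significance flags under Bonferroni control: p < alpha / m."""
    p = np.asarray(pvals, dtype=float)
    m = len(p) if m is None else m
    if m < 1:
        raise ValueError("m must be >= 1")
    return p < alpha / m


def shape_safety_correlations(table: pd.DataFrame, alpha: float = 0.05
                              ) -> pd.DataFrame:
    """Correlate SF_base and SF_tip against the four shape ratios.

    Returns a long-form frame with one row per (bite mode, shape field):
    r, p and the Bonferroni flag at m = 4 within each bite mode.
    """
    if len(table) < 4:
        raise ValueError("need at least 4 models to correlate")
    rows = []
    for sf_col, mode in (("SF_base", "base"), ("SF_tip", "tip")):
        pvals, rvals = [], []
        for f in SHAPE_FIELDS:
            r, p = pearson(table[f], table[sf_col])
            rvals.append(r)
            pvals.append(p)
        flags = bonferroni_flags(pvals, alpha=alpha, m=len(SHAPE_FIELDS))
        for f, r, p, sig in zip(SHAPE_FIELDS, rvals, pvals, flags):
            rows.append(dict(bite_mode=mode, field=f, r=r, p=p,
                             significant=bool(sig)))
    return pd.DataFrame(rows)
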