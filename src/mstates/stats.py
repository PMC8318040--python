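"""High/low group construction and Wilcoxon rank-sum comparisons.

Trials are split on a rating dimension at 4.5 (the midpoint of the 1-9
self-assessment scale); every microstate parameter and every off-diagonal
transition probability is then compared between groups with the two-sided
Wilcoxon rank-sum test, flagged at alpha = 0.05 and 0.10. No correction for
multiple comparisons is applied by default; Benjamini-Hochberg is optional.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import RatingTable

__all__ = [
    "GroupSplit",
    "TestResult",
    "split_high_low",
    "ranksum",
    "compare_parameters",
]

log = logging.getLogger(__name__)

EXACT_N_LIMIT = 20  # combined sample size up to which the exact test is used


@dataclass
class GroupSplit:
    dimension: str
    threshold: float
    assignment: dict  # trial id -> "high" | "low"

    def ids(self, group: str) -> list:
        return [t for t, g in self.assignment.items() if g == group]


@dataclass
class TestResult:
    """Two-sided rank-sum test outcome.

    ``statistic`` is the rank sum W of the smaller sample (ties broken
    toward x).
    """

    statistic: float
    p_value: float
    n_x: int
    n_y: int
    method: str

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1 + 1e-12:
            raise ValueError("p-value out of [0, 1]")


def split_high_low(
    ratings: RatingTable, dimension: str, threshold: float = 4.5
) -> GroupSplit:
    """Assign each rated trial to 'high' (rating > threshold) or 'low'."""
    assignment = {}
    for _, row in ratings.table.iterrows():
        val = row[dimension]
        if pd.isna(val):
            log.warning("trial %r has no %s rating; excluded", row["trial_id"], dimension)
            continue
        assignment[row["trial_id"]] = "high" if val > threshold else "low"
    return GroupSplit(dimension=dimension, threshold=threshold, assignment=assignment)


def ranksum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact p by enumeration of rank assignments when the combined sample size
    is at most 20 and there are no ties; otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w_small = float(ranks[: x.size].sum() if x.size <= y.size else ranks[x.size :].sum())
    has_ties = len(np.unique(pooled)) < pooled.size
    if x.size + y.size <= EXACT_N_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "normal-approximation"
    res = sps.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if method == "exact" else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=w_small,
        p_value=min(float(res.pvalue), 1.0),
        n_x=int(x.size),
        n_y=int(y.size),
        method=method,
    )


_PARAM_RE = re.compile(r"^(dur_ms|occ|cov|gev)\.c(\d+)$")
_TRANS_RE = re.compile(r"^tp\.c(\d+)\.c(\d+)$")


def _describe_column(col: str):
    m = _PARAM_RE.match(col)
    if m:
        return m.group(1), m.group(2)
    m = _TRANS_RE.match(col)
    if m:
        return "tp", f"{m.group(1)}->{m.group(2)}"
    return col, ""


def compare_parameters(
    features: pd.DataFrame,
    split: GroupSplit,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Rank-sum comparison of every feature column between high and low.

    ``features`` must carry a ``trial_id`` column; remaining numeric columns
    are tested. Returns one row per column with group means +- SD, the test
    result, and significance flags at alpha = 0.05 and 0.10. Groups with
    fewer than 2 observations yield p = NaN for that row.
    """
    empty_cols = [
        "parameter", "class", "dimension", "mean_high", "sd_high", "mean_low",
        "sd_low", "n_high", "n_low", "statistic", "p_value", "method",
        "sig_05", "sig_10",
    ]
    high = set(split.ids("high"))
    low = set(split.ids("low"))
    df = features[features["trial_id"].isin(high | low)]
    if df.empty:
        return pd.DataFrame(columns=empty_cols)
    cols = [
        c
        for c in df.columns
        if c not in ("trial_id", "window_id", "subject_id", "valence", "arousal", "dominance")
        and pd.api.types.is_numeric_dtype(df[c])
    ]
    rows = []
    for col in cols:
        xs = df.loc[df["trial_id"].isin(high), col].dropna().to_numpy()
        ys = df.loc[df["trial_id"].isin(low), col].dropna().to_numpy()
        param, cls = _describe_column(col)
        row = {
            "parameter": param,
            "class": cls,
            "dimension": split.dimension,
            "mean_high": xs.mean() if xs.size else np.nan,
            "sd_high": xs.std(ddof=1) if xs.size > 1 else np.nan,
            "mean_low": ys.mean() if ys.size else np.nan,
            "sd_low": ys.std(ddof=1) if ys.size > 1 else np.nan,
            "n_high": xs.size,
            "n_low": ys.size,
        }
        if xs.size < 2 or ys.size < 2:
            row.update(statistic=np.nan, p_value=np.nan, method="NA")
        else:
            res = ranksum(xs, ys)
            row.update(statistic=res.statistic, p_value=res.p_value, method=res.method)
        rows.append(row)
    report = pd.DataFrame(rows)
    if report.empty:
        return pd.DataFrame(columns=empty_cols)
    pvals = report["p_value"].to_numpy()
    if fdr:
        from statsmodels.stats.multitest import multipletests

        ok = ~np.isnan(pvals)
        adj = np.full_like(pvals, np.nan)
        if ok.any():
            adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        report["p_adjusted"] = adj
        pvals = adj
    report["sig_05"] = pvals < 0.05
    report["sig_10"] = pvals < 0.10
    return report
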