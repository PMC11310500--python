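"""Cohort-level aggregation: per-organ/per-patient summaries, signed
method-difference matrices, and paired t-tests.

All averaging skips NaN cells (an undefined metric never drags a mean to
NaN); counts of contributing values are reported alongside.  Sign
convention for differences (method2 - method1): positive overlap
differences and negative distance differences favour method2.  No
multiple-testing correction is applied by default — the clinical analysis
used raw alpha = 0.05 across all organ x metric cells — but Holm
correction is available as an opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import (
    DISTANCE_METRIC_NAMES,
    METRIC_NAMES,
    OVERLAP_METRIC_NAMES,
    CohortMetricTable,
)

__all__ = [
    "EmptyResultError",
    "DifferenceMatrix",
    "PairedTestResult",
    "summarize_by_organ",
    "summarize_by_patient",
    "difference_matrix",
    "paired_test",
    "paired_tests_all",
    "win_tie_loss",
]

_FAMILIES = {
    "overlap": OVERLAP_METRIC_NAMES,
    "distance": DISTANCE_METRIC_NAMES,
}


class EmptyResultError(ValueError):
    """No records match the requested method/selection."""


@dataclass(frozen=True)
class DifferenceMatrix:
    """Signed mean differences (method2 - method1), organs x metrics."""

    values: pd.DataFrame
    method1: str
    method2: str
    family: str


@dataclass(frozen=True)
class PairedTestResult:
    organ: str
    metric: str
    n_pairs: int
    t_statistic: float
    p_value: float
    winner: str  # method label or "no_difference"


def _method_frame(table: CohortMetricTable, method: str) -> pd.DataFrame:
    df = table.df[table.df["method"] == method]
    if df.empty:
        raise EmptyResultError(f"no records for method {method!r}")
    return df


def _pivot_summary(df: pd.DataFrame, index: str) -> pd.DataFrame:
    """Mean / SD / count per (index, metric), NaN-skipping, n-1 SD."""
    g = df.groupby([index, "metric"])["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    wide = out.pivot(index=index, columns="metric")
    present = [m for m in METRIC_NAMES if m in set(out["metric"])]
    return wide.reindex(columns=pd.MultiIndex.from_product([["mean", "sd", "n"], present]))


def summarize_by_organ(table: CohortMetricTable, method: str) -> pd.DataFrame:
    """Cohort mean, SD and count of each metric per organ (NaN-skipping)."""
    return _pivot_summary(_method_frame(table, method), "organ")


def summarize_by_patient(table: CohortMetricTable, method: str) -> pd.DataFrame:
    """Each metric averaged across organs within a patient — one average
    metric per patient, describing how the method contoured that whole
    patient."""
    return _pivot_summary(_method_frame(table, method), "patient_id")


def difference_matrix(
    table: CohortMetricTable, method1: str, method2: str, metric_family: str
) -> DifferenceMatrix:
    """mean(method2) - mean(method1) per (organ, metric) for one family."""
    if metric_family not in _FAMILIES:
        raise ValueError(
            f"metric_family must be one of {sorted(_FAMILIES)}, got {metric_family!r}"
        )
    metrics = list(_FAMILIES[metric_family])
    m1 = summarize_by_organ(table, method1)["mean"]
    m2 = summarize_by_organ(table, method2)["mean"]
    organs = sorted(set(m1.index) | set(m2.index))
    cols = [m for m in metrics if m in m1.columns or m in m2.columns]
    diff = m2.reindex(index=organs, columns=cols) - m1.reindex(index=organs, columns=cols)
    return DifferenceMatrix(values=diff, method1=method1, method2=method2, family=metric_family)


def _better_mean(metric: str, mean1: float, mean2: float) -> int:
    """+1 if method2's mean is better, -1 if method1's, 0 if tied.

    Overlap metrics: higher is better; distance metrics: lower is better.
    """
    if metric in OVERLAP_METRIC_NAMES:
        d = mean2 - mean1
    else:
        d = mean1 - mean2
    return 0 if d == 0 else (1 if d > 0 else -1)


def paired_test(
    table: CohortMetricTable,
    method1: str,
    method2: str,
    organ: str,
    metric: str,
    alpha: float = 0.05,
) -> PairedTestResult:
    """Two-sided paired t-test on per-patient differences for one cell.

    Pairs require both methods non-NaN for the same patient.  Degenerate
    cases follow fixed conventions: fewer than 2 pairs -> p = NaN, winner
    ``no_difference``; zero-variance nonzero differences -> p = 0, winner by
    sign.  The winner is the method with the better mean (higher for
    overlap, lower for distance) when p < alpha.
    """
    df = table.df
    sel = (df["organ"] == organ) & (df["metric"] == metric)
    a = df[sel & (df["method"] == method1)].set_index("patient_id")["value"]
    b = df[sel & (df["method"] == method2)].set_index("patient_id")["value"]
    pairs = pd.concat([a, b], axis=1, keys=["m1", "m2"]).dropna()
    n = len(pairs)
    if n < 2:
        return PairedTestResult(organ, metric, n, np.nan, np.nan, "no_difference")
    d = pairs["m2"].to_numpy() - pairs["m1"].to_numpy()
    sd = d.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(d).max())):  # constant differences
        sd = 0.0
    if sd == 0:
        if d.mean() == 0:
            return PairedTestResult(organ, metric, n, np.nan, np.nan, "no_difference")
        t_stat, p = np.inf * np.sign(d.mean()), 0.0
    else:
        t_stat, p = stats.ttest_rel(pairs["m2"], pairs["m1"])
        t_stat, p = float(t_stat), float(p)
    if np.isnan(p) or p >= alpha:
        winner = "no_difference"
    else:
        side = _better_mean(metric, pairs["m1"].mean(), pairs["m2"].mean())
        winner = {1: method2, -1: method1, 0: "no_difference"}[side]
    return PairedTestResult(organ, metric, n, t_stat, p, winner)


def paired_tests_all(
    table: CohortMetricTable,
    method1: str,
    method2: str,
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Paired t-tests for every (organ, metric) cell present for both methods.

    With ``holm`` the p-values are Holm-adjusted before the winner call
    (off by default, matching the raw-alpha clinical analysis).
    """
    df = table.df
    cells = sorted(
        set(map(tuple, df[df["method"].isin([method1, method2])][["organ", "metric"]].values))
    )
    results = [paired_test(table, method1, method2, o, m, alpha) for o, m in cells]
    out = pd.DataFrame([r.__dict__ for r in results])
    if holm and len(out):
        from statsmodels.stats.multitest import multipletests

        valid = out["p_value"].notna()
        adj = out["p_value"].copy()
        if valid.any():
            adj.loc[valid] = multipletests(out.loc[valid, "p_value"], method="holm")[1]
        out["p_value_adjusted"] = adj
        redo = []
        for r, p_adj in zip(results, adj):
            if np.isnan(p_adj) or p_adj >= alpha:
                redo.append("no_difference")
            else:
                redo.append(r.winner if r.winner != "no_difference" else "no_difference")
        out["winner"] = redo
    return out


def win_tie_loss(
    tests: pd.DataFrame, method1: str, method2: str
) -> dict[str, float]:
    """Tally significant wins per method and ties over organ x metric cells,
    as percentages of all cells tested."""
    n = len(tests)
    if n == 0:
        raise EmptyResultError("no cells to tally")
    w2 = int((tests["winner"] == method2).sum())
    w1 = int((tests["winner"] == method1).sum())
    tie = n - w1 - w2
    return {
        method2: 100.0 * w2 / n,
        method1: 100.0 * w1 / n,
        "no_difference": 100.0 * tie / n,
        "n_cells": n,
    }
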