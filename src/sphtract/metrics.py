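"""Volumetric evaluation suite and paired statistical comparison.

Six voxel-level metrics derived from the confusion counts between a predicted
mask P and a reference mask G:

    Dice        2TP / (2TP + FP + FN)
    VOP         TP / (TP + FN)          volumetric overlap: fraction of the
                                        reference volume recovered
    VOR         FP / (TP + FN)          volumetric overreach: false-positive
                                        volume relative to the reference
    specificity TN / (TN + FP)
    precision   TP / (TP + FP)
    Jaccard     TP / (TP + FP + FN)

VOP and VOR are complementary — high VOP with low VOR means good coverage
without over-segmentation — and satisfy dice = 2*vop / (1 + vop + vor)
whenever the reference is non-empty.  Method comparison uses the two-sided
Wilcoxon signed-rank test on paired per-tract scores with Bonferroni
correction across tracts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

METRIC_NAMES = ("dice", "vop", "vor", "specificity", "precision", "jaccard")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def reference_size(self) -> int:
        return self.tp + self.fn


@dataclass(frozen=True)
class MetricRow:
    """Six metrics for one (prediction, reference) pair.

    On an empty reference, dice/vop/vor are NaN sentinels (undefined), never
    silently 0.
    """

    dice: float
    vop: float
    vor: float
    specificity: float
    precision: float
    jaccard: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def confusion_counts(P: np.ndarray, G: np.ndarray) -> ConfusionCounts:
    """Exact voxel counts between binary prediction P and reference G."""
    P = np.asarray(P)
    G = np.asarray(G)
    if P.shape != G.shape:
        raise ValueError(f"grid mismatch: prediction {P.shape} vs reference {G.shape}")
    p = P.astype(bool)
    g = G.astype(bool)
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return ConfusionCounts(tp, fp, fn, tn)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else np.nan


def compute_metrics(c: ConfusionCounts) -> MetricRow:
    """All six metrics from one set of confusion counts.

    Guarded denominators: an empty reference makes dice/vop/vor NaN; an empty
    prediction makes precision NaN; an all-positive grid makes specificity NaN.
    """
    ref = c.tp + c.fn
    if ref > 0:
        dice = 2.0 * c.tp / (2.0 * c.tp + c.fp + c.fn)
        vop = c.tp / ref
        vor = c.fp / ref
    else:
        dice = vop = vor = np.nan
    return MetricRow(
        dice=dice,
        vop=vop,
        vor=vor,
        specificity=_safe_div(c.tn, c.tn + c.fp),
        precision=_safe_div(c.tp, c.tp + c.fp),
        jaccard=_safe_div(c.tp, c.tp + c.fp + c.fn) if ref + c.fp > 0 else np.nan,
    )


def evaluate_pair(P: np.ndarray, G: np.ndarray) -> MetricRow:
    return compute_metrics(confusion_counts(P, G))


def aggregate(rows: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Mean and sample (n-1) standard deviation of each metric.

    ``rows`` has one row per (subject, tract) with the six metric columns;
    ``by`` groups (e.g. ["tract"]) or, when None, aggregates over everything
    (the grand mean across tracts).  NaN sentinels are excluded and their
    count is reported in ``n_undefined``.
    """
    if rows.empty:
        raise ValueError("no metric rows to aggregate")
    cols = [c for c in METRIC_NAMES if c in rows.columns]
    if not cols:
        raise ValueError("no metric columns found")

    def _summary(df: pd.DataFrame) -> pd.Series:
        out: dict[str, float] = {}
        for c in cols:
            vals = df[c].dropna()
            out[f"{c}_mean"] = vals.mean() if len(vals) else np.nan
            out[f"{c}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        out["n"] = len(df)
        out["n_undefined"] = int(df[cols].isna().any(axis=1).sum())
        return pd.Series(out)

    if by:
        return rows.groupby(by, sort=True).apply(_summary, include_groups=False)
    return _summary(rows).to_frame().T


def compare_methods(
    scores_a: np.ndarray, scores_b: np.ndarray, n_comparisons: int = 1
) -> tuple[float, float, float]:
    """Two-sided Wilcoxon signed-rank test on paired scores, Bonferroni-adjusted.

    Zero differences are dropped (Wilcoxon's convention); the exact null
    distribution is used for n <= 25 remaining pairs, the normal
    approximation with continuity correction above.  Returns
    ``(statistic, p_raw, p_adjusted)`` with p_adjusted = min(1, m * p_raw).
    If every difference is zero the methods are indistinguishable and p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired score vectors must be 1D and equal length")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    diffs = a - b
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return 0.0, 1.0, 1.0
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                         correction=(method == "approx"), method=method)
    p_raw = float(res.pvalue)
    return float(res.statistic), p_raw, min(1.0, n_comparisons * p_raw)
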