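"""Evaluation machinery: confusion metrics, ROC/AUC, cumulative percentage,
feature correlations, class statistics, Wilcoxon signed-rank and DeLong tests.

Conventions fixed here because reported numbers depend on them:

* Sensitivity (recall) = TP/(TP+FN), specificity = TN/(TN+FP), precision =
  TP/(TP+FP), F1 = harmonic mean of precision and recall, accuracy =
  (TP+TN)/total.  Report tables round half-away-from-zero to 2 decimals.
* Quantiles use linear interpolation between order statistics.
* The cumulative-percentage comparison takes the reference channel as the
  percentage-difference denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "ROCCurve",
    "TestResult",
    "CumPResult",
    "metrics_from_counts",
    "confusion_from_predictions",
    "roc_auc",
    "cumulative_percentage",
    "cumulative_percentage_from_pct",
    "feature_correlations",
    "class_statistics",
    "wilcoxon_signed_rank",
    "delong_test",
    "round2",
]


def round2(x: float) -> float:
    """Round half away from zero to 2 decimals (report-table display rule)."""
    return math.floor(abs(x) * 100 + 0.5 + 1e-12) / 100 * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("all-zero confusion counts")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    accuracy: float

    def rounded(self) -> "MetricSet":
        return MetricSet(*(round2(v) for v in (
            self.sensitivity, self.specificity, self.precision, self.f1, self.accuracy
        )))


def metrics_from_counts(c: ConfusionCounts) -> MetricSet:
    """Derived proportions from a 2x2 confusion table.

    A metric whose denominator is zero is returned as NaN (flagged
    undefined) rather than raising.
    """

    def safe(num, den):
        return num / den if den > 0 else float("nan")

    sens = safe(c.tp, c.tp + c.fn)
    spec = safe(c.tn, c.tn + c.fp)
    prec = safe(c.tp, c.tp + c.fp)
    f1 = (
        2 * prec * sens / (prec + sens)
        if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
        else float("nan")
    )
    acc = (c.tp + c.tn) / c.total
    return MetricSet(sens, spec, prec, f1, acc)


def confusion_from_predictions(preds, positive: int = 1) -> ConfusionCounts:
    """Confusion counts from a PredictionSet-like object (y_true, y_pred)."""
    yt = np.asarray(preds.y_true) == positive
    yp = np.asarray(preds.y_pred) == positive
    return ConfusionCounts(
        tp=int(np.sum(yt & yp)),
        fn=int(np.sum(yt & ~yp)),
        fp=int(np.sum(~yt & yp)),
        tn=int(np.sum(~yt & ~yp)),
    )


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(y_true, score) -> ROCCurve:
    """ROC curve by threshold sweep and AUC by trapezoidal integration.

    With score ties the AUC equals the rank-averaged Mann-Whitney
    statistic.  Accepts either two arrays or a PredictionSet (pass its
    y_true/score).
    """
    y = np.asarray(y_true)
    s = np.asarray(score, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite scores")
    fpr, tpr, thr = _sk_roc_curve(y, s)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)))


@dataclass
class CumPResult:
    """Per-sample cumulative-percentage bookkeeping (one comparison column)."""

    abs_diff: np.ndarray | None
    pct_diff: np.ndarray
    indicator: np.ndarray
    count: np.ndarray
    cum_pct: np.ndarray
    threshold_pct: float

    @property
    def final(self) -> float:
        return float(self.cum_pct[-1])


def cumulative_percentage_from_pct(
    pct_diff, threshold_pct: float, abs_diff=None
) -> CumPResult:
    """Cumulative percentage from a precomputed percentage-difference column.

    indicator_i = (pct_diff_i <= threshold); count_i = running indicator sum;
    CP_i = 100 x count_i / i.
    """
    p = np.asarray(pct_diff, dtype=float)
    ind = (p <= threshold_pct).astype(int)
    count = np.cumsum(ind)
    cp = 100.0 * count / np.arange(1, len(p) + 1)
    return CumPResult(
        abs_diff=None if abs_diff is None else np.asarray(abs_diff, float),
        pct_diff=p,
        indicator=ind,
        count=count,
        cum_pct=cp,
        threshold_pct=threshold_pct,
    )


def cumulative_percentage(ref, test, threshold_pct: float) -> CumPResult:
    """Cumulative percentage of agreement between a reference and a test
    channel: per-sample percentage absolute difference 100|ref-test|/ref,
    thresholded, counted cumulatively.

    Samples with a zero reference value have an undefined percentage
    difference and are excluded (flagged NaN in ``pct_diff``).
    """
    r = np.asarray(ref, dtype=float)
    s = np.asarray(test, dtype=float)
    if r.shape != s.shape:
        raise ValueError("ref and test must have equal length")
    ok = r != 0
    ad = np.abs(r - s)
    pct = np.full(len(r), np.nan)
    pct[ok] = 100.0 * ad[ok] / np.abs(r[ok])
    res = cumulative_percentage_from_pct(pct[ok], threshold_pct, abs_diff=ad[ok])
    res.pct_diff = pct  # keep full-length column with NaN flags
    return res


def average_cumP(refs, tests, threshold_pct: float) -> np.ndarray:
    """Average cumulative-percentage curve over paired (x, y) channels and
    subjects: per subject the x and y CP curves are averaged, then curves
    are averaged across subjects (curves must share a common length)."""
    curves = []
    for (rx, ry), (sx, sy) in zip(refs, tests):
        cx = cumulative_percentage(rx, sx, threshold_pct).cum_pct
        cy = cumulative_percentage(ry, sy, threshold_pct).cum_pct
        curves.append((cx + cy) / 2.0)
    return np.mean(curves, axis=0)


def feature_correlations(featA: pd.DataFrame, featB: pd.DataFrame) -> pd.DataFrame:
    """Per-feature Pearson r and two-sided p between matched tables.

    A zero-variance column yields NaN r (flagged undefined).
    """
    from .features import FEATURE_NAMES

    shared = [c for c in FEATURE_NAMES if c in featA.columns and c in featB.columns]
    if len(featA) != len(featB):
        raise ValueError("feature tables must have matched rows")
    rows = []
    for c in shared:
        a = featA[c].to_numpy(float)
        b = featB[c].to_numpy(float)
        if np.std(a) == 0 or np.std(b) == 0:
            rows.append({"feature": c, "r": np.nan, "p": np.nan})
        else:
            r, p = stats.pearsonr(a, b)
            rows.append({"feature": c, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def class_statistics(features: pd.DataFrame) -> pd.DataFrame:
    """Per-class, per-feature MAX/MIN/AVG/STD plus the five-number box-plot
    summary (quartiles by linear interpolation between order statistics)."""
    from .features import FEATURE_NAMES

    rows = []
    for label, grp in features.groupby("label"):
        for c in FEATURE_NAMES:
            v = grp[c].to_numpy(float)
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            rows.append(
                {
                    "label": int(label),
                    "feature": c,
                    "max": float(np.max(v)),
                    "min": float(np.min(v)),
                    "avg": float(np.mean(v)),
                    "std": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                    "q1": float(q1),
                    "median": float(med),
                    "q3": float(q3),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TestResult:
    z: float
    p: float
    h: int  # 1 iff p < 0.05
    statistic: float

    def to_dict(self) -> dict:
        return {"z": self.z, "p": self.p, "H": self.h, "statistic": self.statistic}


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Wilcoxon signed-rank test on paired series.

    p-value: exact enumeration for small samples without ties/zeros,
    normal approximation otherwise; the z-score is always reported from
    the normal approximation (zeros discarded, ties mid-ranked).  All-zero
    differences give a degenerate flagged result with H = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired series must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(z=0.0, p=1.0, h=0, statistic=0.0)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    mu = n * (n + 1) / 4.0
    # tie correction in the variance
    _, counts = np.unique(ranks, return_counts=True)
    tie = np.sum(counts**3 - counts) / 48.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie)
    z = 0.0 if sigma == 0 else (w_plus - mu) / sigma
    res = stats.wilcoxon(x, y, zero_method="wilcox", correction=False, method="auto")
    p = float(res.pvalue)
    return TestResult(z=float(z), p=p, h=int(p < 0.05), statistic=w_plus)


def _delong_components(y_true, score) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components (V10 per positive, V01 per
    negative) using mid-ranks, so ties contribute 1/2."""
    y = np.asarray(y_true)
    s = np.asarray(score, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes required")
    # psi(pos_i, neg_j) = 1 if pos>neg, 0.5 if equal, 0 otherwise
    cmp_ = (pos[:, None] > neg[None, :]).astype(float)
    cmp_ += 0.5 * (pos[:, None] == neg[None, :])
    auc = float(cmp_.mean())
    v10 = cmp_.mean(axis=1)  # per positive
    v01 = cmp_.mean(axis=0)  # per negative
    return auc, v10, v01


def delong_test(predsA, predsB) -> TestResult:
    """DeLong test for the difference of two correlated AUCs.

    Both prediction sets must score the same samples with the same true
    labels.  z = (AUC_A - AUC_B) / se, with the paired variance from the
    structural components; two-sided p.  A model against itself returns
    exactly z = 0, p = 1.
    """
    yA = np.asarray(predsA.y_true)
    yB = np.asarray(predsB.y_true)
    if yA.shape != yB.shape or np.any(yA != yB):
        raise ValueError("prediction sets must cover the same samples/labels")
    sA = np.asarray(predsA.score, dtype=float)
    sB = np.asarray(predsB.score, dtype=float)
    aucA, v10A, v01A = _delong_components(yA, sA)
    aucB, v10B, v01B = _delong_components(yB, sB)
    m = len(v10A)
    n = len(v01A)

    def cov(a, b):
        return float(np.sum((a - a.mean()) * (b - b.mean())) / (len(a) - 1))

    s10 = cov(v10A, v10A) + cov(v10B, v10B) - 2 * cov(v10A, v10B)
    s01 = cov(v01A, v01A) + cov(v01B, v01B) - 2 * cov(v01A, v01B)
    var = s10 / m + s01 / n
    delta = aucA - aucB
    if var <= 0:
        z = 0.0
        p = 1.0 if delta == 0 else 0.0
    else:
        z = delta / math.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return TestResult(z=float(z), p=p, h=int(p < 0.05), statistic=float(delta))
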