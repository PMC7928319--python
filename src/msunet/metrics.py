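"""Segmentation evaluation measures and fold statistics.

Pixel-overlap metrics are computed from pooled confusion counts:

    IoU       = TP / (TP + FP + FN)
    Dice      = 2*TP / (2*TP + FP + FN)
    Precision = TP / (TP + FP)

ROC AUC is computed on raw per-pixel probabilities.  Fold-level results are
summarized as mean +/- sample standard deviation, and architectures are
compared with the classical pooled-variance two-sample t-test.

Degenerate denominators follow the common benchmark convention: a metric is
1.0 when prediction and truth are both empty, 0.0 otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "ConfusionCounts", "MetricReport", "confusion_counts", "iou", "dice",
    "precision", "roc_auc", "roc_points", "two_sample_t_test",
    "aggregate_folds", "results_table", "write_results",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of a binary prediction against ground truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def confusion_counts(pred_mask: np.ndarray, truth_mask: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred_mask)
    truth = np.asarray(truth_mask)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    for name, arr in (("prediction", pred), ("truth", truth)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} mask must contain only 0/1 values")
    pred = pred.astype(bool)
    truth = truth.astype(bool)
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    return ConfusionCounts(tp, fp, fn, pred.size - tp - fp - fn)


def _ratio(num: int, den: int) -> float:
    if den == 0:
        return 1.0  # both masks empty: nothing was missed
    return num / den


def iou(c: ConfusionCounts) -> float:
    """Intersection over union (Jaccard index)."""
    return _ratio(c.tp, c.tp + c.fp + c.fn)


def dice(c: ConfusionCounts) -> float:
    """Dice similarity coefficient (F1 over pixels)."""
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)


def precision(c: ConfusionCounts) -> float:
    """Fraction of predicted foreground that is truly foreground."""
    return _ratio(c.tp, c.tp + c.fp)


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Area under the ROC curve of per-pixel scores (0.5 = uninformative)."""
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth).ravel()
    classes = np.unique(truth)
    if not np.isin(classes, (0, 1)).all():
        raise ValueError("truth mask must be binary")
    if classes.size < 2:
        raise ValueError("ROC AUC is undefined for single-class truth")
    return float(roc_auc_score(truth, scores))


def roc_points(scores: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """ROC curve samples (FPR, TPR, threshold) for plotting/export."""
    fpr, tpr, thr = roc_curve(np.asarray(truth).ravel(),
                              np.asarray(scores, dtype=float).ravel())
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def two_sample_t_test(a, b) -> tuple[float, float]:
    """Independent two-sample t-test with pooled variance; returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0  # identical constant samples: no evidence of difference
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


@dataclass
class MetricReport:
    """Per-fold values of one metric with their mean +/- SD summary."""

    metric: str
    values: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not self.values:
            raise ValueError("need at least one value")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        # sample SD (n-1); a single fold has no spread
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0

    def __str__(self) -> str:
        return f"{self.metric}: {self.mean:.3f} ± {self.sd:.3f}"


def aggregate_folds(values, metric: str = "IoU") -> MetricReport:
    return MetricReport(metric=metric, values=[float(v) for v in values])


# ---------------------------------------------------------------------------
# tabular export (ablation-table shape: rows = architectures, M +/- SD cells)
# ---------------------------------------------------------------------------

def results_table(rows: dict[str, dict[str, MetricReport]],
                  p_values: dict[str, float] | None = None) -> pd.DataFrame:
    """rows: architecture -> metric name -> MetricReport."""
    records = []
    for arch, metrics in rows.items():
        rec: dict = {"architecture": arch}
        for name, rep in metrics.items():
            rec[f"{name}_mean"] = rep.mean
            rec[f"{name}_sd"] = rep.sd
            rec[name] = f"{rep.mean:.3f} ± {rep.sd:.3f}"
        if p_values is not None and arch in p_values:
            rec["p_value"] = p_values[arch]
        records.append(rec)
    return pd.DataFrame.from_records(records)


def write_results(rows, path, p_values=None) -> None:
    """Write an ablation table as CSV or JSON depending on the suffix."""
    df = results_table(rows, p_values)
    path = str(path)
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=2)
    else:
        df.to_csv(path, index=False)
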