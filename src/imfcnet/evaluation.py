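"""Metrics, fold aggregation, paired t-tests, and comparison reports.

Conventions (chosen to match the reporting style of the ten-fold protocol):

* ACC is the overall fraction correct (confusion-matrix trace over total).
* AP / AR are unweighted macro averages of per-class one-vs-rest precision
  and recall; a class never predicted contributes precision 0 (warned).
* F1 is the harmonic mean of AP and AR computed per fold, and fold-wise F1
  values are then averaged (the alternative — F1 of the averaged AP/AR — is
  exposed separately, because the two differ in general).
* Aggregation is mean +- sample standard deviation (n-1).
* Model pairs sharing fold splits are compared with two-sided paired
  t-tests per metric; the four p-values are additionally averaged, with
  verdicts at the 0.05 and 0.01 levels.

All percentages are on the 0-100 scale.  Report rounding is half-up,
2 decimals for metrics and 4 for p-values; raw values are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

METRICS = ("acc", "ap", "ar", "f1")


def round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class_tally(self) -> pd.DataFrame:
        """One-vs-rest TP/FP/FN/TN per class (each row sums to the total)."""
        c = self.counts
        tp = np.diag(c)
        fp = c.sum(axis=0) - tp
        fn = c.sum(axis=1) - tp
        tn = self.total - tp - fp - fn
        return pd.DataFrame({"TP": tp, "FP": fp, "FN": fn, "TN": tn},
                            index=list(self.labels))

    def row_normalized(self) -> np.ndarray:
        """Row percentages; the diagonal is the per-class recall."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = 100.0 * self.counts / sums
        return np.where(sums > 0, out, 0.0)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.counts, index=list(self.labels),
                     columns=list(self.labels)).to_csv(path)


def confusion(y_true, y_pred, labels) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    unknown = set(np.unique(y_true)) | set(np.unique(y_pred))
    unknown -= set(labels)
    if unknown:
        raise ValueError(f"labels not in catalogue: {sorted(unknown)}")
    counts = _sk_confusion(y_true, y_pred, labels=list(labels))
    return ConfusionMatrix(counts, tuple(labels))


@dataclass
class FoldMetrics:
    acc: float
    ap: float
    ar: float
    f1: float
    cm: ConfusionMatrix | None = None
    fold_id: int | None = None
    model_tag: str = ""

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRICS}


def metrics_from_cm(cm: ConfusionMatrix) -> FoldMetrics:
    """ACC / macro AP / macro AR / harmonic F1 from one confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tally = cm.per_class_tally()
    tp, fp, fn = tally["TP"].values, tally["FP"].values, tally["FN"].values
    pred_pos = tp + fp
    if (pred_pos == 0).any():
        missing = [cm.labels[i] for i in np.flatnonzero(pred_pos == 0)]
        warnings.warn(
            f"class(es) never predicted, precision taken as 0: {missing}")
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_pos > 0, tp / np.maximum(pred_pos, 1), 0.0)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
    acc = 100.0 * np.trace(cm.counts) / cm.total
    ap = 100.0 * float(precision.mean())
    ar = 100.0 * float(recall.mean())
    f1 = (2 * ap * ar / (ap + ar)) if (ap + ar) > 0 else 0.0
    return FoldMetrics(acc=float(acc), ap=ap, ar=ar, f1=float(f1), cm=cm)


def aggregate(folds: list[FoldMetrics]) -> dict[str, tuple[float, float]]:
    """Per-metric (mean, sample std).  A single fold reports std 0."""
    if not folds:
        raise ValueError("no folds to aggregate")
    out = {}
    for m in METRICS:
        vals = np.array([getattr(f, m) for f in folds], dtype=float)
        if len(vals) == 1:
            warnings.warn("single fold: std reported as 0")
            out[m] = (float(vals[0]), 0.0)
        else:
            out[m] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


def f1_of_means(folds: list[FoldMetrics]) -> float:
    """The alternative F1: harmonic mean of the fold-averaged AP and AR."""
    agg = aggregate(folds)
    ap, ar = agg["ap"][0], agg["ar"][0]
    return 2 * ap * ar / (ap + ar) if (ap + ar) > 0 else 0.0


@dataclass
class ComparisonReport:
    p_values: dict[str, float]
    average_p: float
    verdict: str
    gains: dict[str, float]
    means_a: dict[str, tuple[float, float]]
    means_b: dict[str, tuple[float, float]]
    paired: bool = True

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for m in METRICS:
            rows.append({
                "metric": m.upper(),
                "model_a": f"{round_half_up(self.means_a[m][0], 2):.2f} "
                           f"± {round_half_up(self.means_a[m][1], 2):.2f}",
                "model_b": f"{round_half_up(self.means_b[m][0], 2):.2f} "
                           f"± {round_half_up(self.means_b[m][1], 2):.2f}",
                "gain": round_half_up(self.gains[m], 2),
                "p_value": round_half_up(self.p_values[m], 4),
            })
        return pd.DataFrame(rows)


def _verdict(average_p: float) -> str:
    if average_p < 0.01:
        return "99% confidence"
    if average_p < 0.05:
        return "95% confidence"
    return "not significant"


def average_p_value(p_values) -> float:
    """Arithmetic mean of the per-metric p-values."""
    return float(np.mean(list(p_values)))


def paired_ttest(model_a_folds: list[FoldMetrics],
                 model_b_folds: list[FoldMetrics],
                 paired: bool = True) -> ComparisonReport:
    """Two-sided t-test per metric across folds, plus the averaged p-value.

    Folds must pair up (same count, same fold ids when set).  Zero variance
    of the differences yields p = 1 with a warning.
    """
    if len(model_a_folds) != len(model_b_folds):
        raise ValueError("fold lists must have equal length")
    ids_a = [f.fold_id for f in model_a_folds]
    ids_b = [f.fold_id for f in model_b_folds]
    if paired and None not in ids_a and None not in ids_b and ids_a != ids_b:
        raise ValueError(f"fold ids differ between models: {ids_a} vs {ids_b}")
    p_values = {}
    for m in METRICS:
        a = np.array([getattr(f, m) for f in model_a_folds], dtype=float)
        b = np.array([getattr(f, m) for f in model_b_folds], dtype=float)
        if paired:
            d = a - b
            if np.allclose(d.std(ddof=0), 0.0):
                warnings.warn(f"zero variance of paired differences for {m}; "
                              "p reported as 1")
                p_values[m] = 1.0
                continue
            p = stats.ttest_rel(a, b).pvalue
        else:
            p = stats.ttest_ind(a, b).pvalue
        p_values[m] = float(p)
    means_a = aggregate(model_a_folds)
    means_b = aggregate(model_b_folds)
    gains = gain_report({m: means_a[m][0] for m in METRICS},
                        {m: means_b[m][0] for m in METRICS})
    avg = average_p_value(p_values.values())
    return ComparisonReport(p_values, avg, _verdict(avg), gains,
                            means_a, means_b, paired=paired)


def gain_report(means_a: dict[str, float],
                means_b: dict[str, float]) -> dict[str, float]:
    """Elementwise mean difference (model A minus model B), in points."""
    if set(means_a) != set(means_b):
        raise ValueError("metric sets differ")
    return {m: float(means_a[m]) - float(means_b[m]) for m in means_a}


def report_table(results: dict[str, list[FoldMetrics]]) -> pd.DataFrame:
    """Rows of 'model, ACC+-Std, AP+-Std, AR+-Std, F1+-Std' (percent)."""
    rows = []
    for model, folds in results.items():
        agg = aggregate(folds)
        row = {"model": model}
        for m in METRICS:
            mean, std = agg[m]
            row[m.upper() + " ± Std"] = (
                f"{round_half_up(mean, 2):.2f} ± {round_half_up(std, 2):.2f}")
        rows.append(row)
    return pd.DataFrame(rows)


def class_imbalance_percent(larger: int, smaller: int) -> float:
    """How many more samples the larger class has, as a percentage of the
    larger class: 100 * (larger - smaller) / larger."""
    if larger <= 0:
        raise ValueError("larger class count must be positive")
    return 100.0 * (larger - smaller) / larger
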