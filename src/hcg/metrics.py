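"""Classification evaluation: confusion counts, ROC/PR curves and areas,
one-vs-rest multiclass extension, and cross-tabulation of two label sets.

Overall (multiclass) scores are unweighted means of the per-subtype
one-vs-rest scores.  ROC areas use the trapezoid (Mann-Whitney, ties
counted 1/2) convention; PR areas use the step-wise non-interpolated sum
sum_i (r_i - r_{i-1}) * precision_i.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence
import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)

from .omics_io import SUBTYPES


class MetricsError(ValueError):
    pass


@dataclass
class MetricsReport:
    """Per-subtype and overall classification scores plus a confusion matrix."""

    per_class: pd.DataFrame      # index: subtype; columns: auROC, auPRC, accuracy, F1
    overall: pd.Series           # unweighted class means of the four columns
    confusion: pd.DataFrame      # 4x4 counts, rows = truth, cols = prediction
    classifier: str = ""

    def to_json(self, path=None) -> str:
        payload = {
            "classifier": self.classifier,
            "per_class": {c: {m: _none_if_nan(v) for m, v in row.items()}
                          for c, row in self.per_class.iterrows()},
            "overall": {m: _none_if_nan(v) for m, v in self.overall.items()},
            "confusion": self.confusion.to_dict(),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_tsv(self, path=None) -> pd.DataFrame:
        """Flat (classifier, subtype, metric, score, overall) table."""
        rows = []
        for subtype, row in self.per_class.iterrows():
            for metric, score in row.items():
                rows.append({"classifier": self.classifier, "subtype": subtype,
                             "metric": metric, "score": score,
                             "overall": self.overall[metric]})
        df = pd.DataFrame(rows)
        if path is not None:
            df.to_csv(path, sep="\t", index=False)
        return df


def _none_if_nan(v):
    return None if (isinstance(v, float) and np.isnan(v)) else float(v)


# ---------------------------------------------------------------------------
# binary building blocks

def binary_counts(y_true: Sequence[int], y_pred: Sequence[int]
                  ) -> tuple[int, int, int, int]:
    """Confusion counts (TP, FP, FN, TN) for 0/1 labels."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.size == 0:
        raise MetricsError("empty input")
    if t.shape != p.shape:
        raise MetricsError("length mismatch")
    tp = int(np.sum((t == 1) & (p == 1)))
    fp = int(np.sum((t == 0) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    tn = int(np.sum((t == 0) & (p == 0)))
    return tp, fp, fn, tn


def accuracy_f1(counts: tuple[int, int, int, int]
                ) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F1) from confusion counts.

    Precision, recall and F1 are 0 by convention when their denominator is 0.
    """
    tp, fp, fn, tn = counts
    total = tp + fp + fn + tn
    if total == 0:
        raise MetricsError("empty confusion counts")
    accuracy = (tp + tn) / total
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return accuracy, precision, recall, f1


def roc_curve_auc(y_true: Sequence[int], scores: Sequence[float]
                  ) -> tuple[pd.DataFrame, float]:
    """ROC staircase (FPR, TPR per threshold) and trapezoidal area."""
    t = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(t)) < 2:
        raise MetricsError("both classes must be present for ROC")
    fpr, tpr, thr = roc_curve(t, s)
    auc = float(roc_auc_score(t, s))
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr}), auc


def pr_curve_auc(y_true: Sequence[int], scores: Sequence[float]
                 ) -> tuple[pd.DataFrame, float]:
    """Precision-recall points and the step-wise (non-interpolated) area."""
    t = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if t.sum() == 0:
        raise MetricsError("at least one positive required for PR")
    precision, recall, thr = precision_recall_curve(t, s)
    auprc = float(average_precision_score(t, s))
    curve = pd.DataFrame({"recall": recall[:-1][::-1],
                          "precision": precision[:-1][::-1],
                          "threshold": thr[::-1]})
    return curve, auprc


# ---------------------------------------------------------------------------
# multiclass

def evaluate_multiclass(y_true: Sequence[str], proba: pd.DataFrame,
                        y_pred: Optional[Sequence[str]] = None,
                        classifier: str = "",
                        classes: Sequence[str] = SUBTYPES) -> MetricsReport:
    """One-vs-rest evaluation of 4-class probabilities.

    For each subtype, ROC/PR areas come from that subtype's probability
    column against the binarised truth; accuracy and F1 come from the hard
    argmax predictions, also binarised one-vs-rest.  A subtype absent from
    the truth has undefined areas: it is reported as NaN and excluded from
    the overall mean, with a warning.
    """
    y_true = pd.Series(list(y_true))
    proba = proba[list(classes)]
    if not np.allclose(proba.sum(axis=1), 1.0, atol=1e-6):
        raise MetricsError("probability rows must sum to 1")
    if y_pred is None:
        y_pred = proba.idxmax(axis=1).to_numpy()
    y_pred = pd.Series(list(y_pred))

    rows = {}
    for cls in classes:
        truth_bin = (y_true == cls).astype(int).to_numpy()
        pred_bin = (y_pred == cls).astype(int).to_numpy()
        acc, _, _, f1 = accuracy_f1(binary_counts(truth_bin, pred_bin))
        if truth_bin.sum() == 0 or truth_bin.sum() == truth_bin.size:
            warnings.warn(f"subtype {cls} absent from one side of the truth; "
                          "auROC/auPRC undefined")
            auroc = auprc = np.nan
        else:
            _, auroc = roc_curve_auc(truth_bin, proba[cls].to_numpy())
            _, auprc = pr_curve_auc(truth_bin, proba[cls].to_numpy())
        rows[cls] = {"auROC": auroc, "auPRC": auprc, "accuracy": acc, "F1": f1}
    per_class = pd.DataFrame.from_dict(rows, orient="index").loc[list(classes)]
    overall = per_class.mean(axis=0, skipna=True)
    confusion = cross_tabulate(y_true, y_pred, classes=classes)[0]
    return MetricsReport(per_class=per_class, overall=overall,
                         confusion=confusion, classifier=classifier)


def cross_tabulate(labels_a: Sequence[str], labels_b: Sequence[str],
                   classes: Sequence[str] = SUBTYPES
                   ) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Counts of (a, b) label pairs, row percentages, and the switch rate
    (off-diagonal fraction) between two subtype assignments of one cohort."""
    a = pd.Categorical(list(labels_a), categories=classes)
    b = pd.Categorical(list(labels_b), categories=classes)
    counts = pd.crosstab(a, b, dropna=False)
    counts = counts.reindex(index=classes, columns=classes, fill_value=0)
    counts.index.name = "a"
    counts.columns.name = "b"
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = counts.div(row_sums, axis=0) * 100.0
    n = counts.to_numpy().sum()
    switch_rate = float((n - np.trace(counts.to_numpy())) / n) if n else 0.0
    return counts, pct, switch_rate
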