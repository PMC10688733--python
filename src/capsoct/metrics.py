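"""Evaluation metrics for multiclass one-vs-rest classification.

Confusion matrix (rows = true class, columns = predicted), per-class
sensitivity/precision/specificity/one-vs-rest accuracy, one-vs-rest ROC and
precision-recall curves with AUC, and the overall summaries:

    OA = correctly classified / total          (micro accuracy)
    OS = unweighted (macro) mean of per-class sensitivity
    OP = unweighted (macro) mean of per-class precision

Note on naming: in parts of the applied literature the per-class "accuracy"
column actually reports recall.  Both quantities are therefore emitted under
unambiguous names: ``acc_ovr`` (one-vs-rest accuracy, (TP+TN)/total) and
``se`` (sensitivity = recall).  Ratios with zero denominators are reported as
0 and flagged in ``MetricsReport.warnings``.

Counting and curve construction delegate to scikit-learn
(`confusion_matrix`, `roc_curve`, `roc_auc_score`, `precision_recall_curve`);
the derived per-class and overall arithmetic is explicit here.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    confusion_matrix as _sk_confusion,
    precision_recall_curve as _sk_pr,
    roc_auc_score as _sk_auc,
    roc_curve as _sk_roc,
)

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "per_class_metrics",
    "overall",
    "roc_auc",
    "pr_curves",
    "build_report",
    "write_report",
    "read_report",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (k, k) ints; rows true, cols predicted
    class_names: tuple[str, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k) or np.any(self.counts < 0):
            raise ValueError("counts must be a (k, k) non-negative matrix")

    @property
    def total(self):
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    class_names: tuple[str, ...]
    confusion: list  # k x k list of ints (JSON-friendly)
    per_class: dict  # name -> {se, pr, sp, acc_ovr, auc}
    oa: float
    os: float
    op: float
    roc_points: dict = field(default_factory=dict)  # name -> {fpr, tpr}
    pr_points: dict = field(default_factory=dict)  # name -> {recall, precision}
    warnings: list = field(default_factory=list)


def confusion(y_true, y_pred, class_names):
    """k x k confusion matrix; counts[i, j] = #(true == i and pred == j)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    k = len(class_names)
    if np.any((y_true < 0) | (y_true >= k)) or np.any((y_pred < 0) | (y_pred >= k)):
        raise ValueError(f"labels must lie in [0, {k})")
    counts = _sk_confusion(y_true, y_pred, labels=np.arange(k))
    return ConfusionMatrix(counts=counts, class_names=tuple(class_names))


def _safe_div(num, den, what, warnings):
    if den == 0:
        warnings.append(f"{what}: zero denominator, reported as 0")
        return 0.0
    return num / den


def per_class_metrics(cm: ConfusionMatrix, warnings=None):
    """One-vs-rest SE, PR, SP and ACC per class, from the confusion counts.

    SE = TP/(TP+FN), PR = TP/(TP+FP), SP = TN/(TN+FP),
    ACC (one-vs-rest) = (TP+TN)/total.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if warnings is None:
        warnings = []
    c = cm.counts.astype(np.float64)
    total = c.sum()
    out = {}
    for i, name in enumerate(cm.class_names):
        tp = c[i, i]
        fn = c[i].sum() - tp
        fp = c[:, i].sum() - tp
        tn = total - tp - fn - fp
        out[name] = {
            "se": _safe_div(tp, tp + fn, f"SE[{name}]", warnings),
            "pr": _safe_div(tp, tp + fp, f"PR[{name}]", warnings),
            "sp": _safe_div(tn, tn + fp, f"SP[{name}]", warnings),
            "acc_ovr": (tp + tn) / total,
        }
    return out, warnings


def overall(cm: ConfusionMatrix, per_class=None):
    """(OA, OS, OP): micro accuracy and macro means of SE and PR."""
    if per_class is None:
        per_class, _ = per_class_metrics(cm)
    oa = np.trace(cm.counts) / cm.total
    os_ = float(np.mean([m["se"] for m in per_class.values()]))
    op = float(np.mean([m["pr"] for m in per_class.values()]))
    return float(oa), os_, op


def roc_auc(scores, y_true, class_names, warnings=None):
    """One-vs-rest ROC curves and AUCs from per-class scores.

    scores : (n, k) finite scores (e.g. capsule lengths).
    Returns (auc: name -> float | None, points: name -> {fpr, tpr}).
    AUC uses the rank statistic with midrank tie handling (equivalent to
    trapezoidal integration of the empirical ROC).  A class with no positive
    or no negative samples has undefined AUC: reported as None and flagged.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y_true = np.asarray(y_true)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if warnings is None:
        warnings = []
    aucs, points = {}, {}
    for i, name in enumerate(class_names):
        pos = (y_true == i).astype(int)
        if pos.sum() == 0 or pos.sum() == len(pos):
            warnings.append(f"AUC[{name}]: degenerate class (undefined)")
            aucs[name] = None
            points[name] = {"fpr": [], "tpr": []}
            continue
        fpr, tpr, _ = _sk_roc(pos, scores[:, i])
        aucs[name] = float(_sk_auc(pos, scores[:, i]))
        points[name] = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
    return aucs, points


def pr_curves(scores, y_true, class_names, warnings=None):
    """One-vs-rest precision-recall curve points per class."""
    scores = np.asarray(scores, dtype=np.float64)
    y_true = np.asarray(y_true)
    if warnings is None:
        warnings = []
    points = {}
    for i, name in enumerate(class_names):
        pos = (y_true == i).astype(int)
        if pos.sum() == 0:
            warnings.append(f"PR curve[{name}]: no positives (undefined)")
            points[name] = {"recall": [], "precision": []}
            continue
        precision, recall, _ = _sk_pr(pos, scores[:, i])
        points[name] = {"recall": recall.tolist(), "precision": precision.tolist()}
    return points


def build_report(y_true, y_pred, scores=None, class_names=None):
    """Assemble the full :class:`MetricsReport` from labels and scores."""
    if class_names is None:
        k = int(max(np.max(y_true), np.max(y_pred))) + 1
        class_names = tuple(str(i) for i in range(k))
    cm = confusion(y_true, y_pred, class_names)
    warnings = []
    per_class, warnings = per_class_metrics(cm, warnings)
    oa, os_, op = overall(cm, per_class)
    roc_points, pr_points = {}, {}
    if scores is not None:
        aucs, roc_points = roc_auc(scores, y_true, class_names, warnings)
        pr_points = pr_curves(scores, y_true, class_names, warnings)
        for name in class_names:
            per_class[name]["auc"] = aucs[name]
    return MetricsReport(
        class_names=tuple(class_names),
        confusion=cm.counts.tolist(),
        per_class=per_class,
        oa=oa,
        os=os_,
        op=op,
        roc_points=roc_points,
        pr_points=pr_points,
        warnings=warnings,
    )


def write_report(report: MetricsReport, out_dir, stem="metrics"):
    """Write ``<stem>.json`` plus confusion/ROC/PR CSVs; returns the JSON path."""
    os.makedirs(out_dir, exist_ok=True)
    payload = {
        "class_names": list(report.class_names),
        "confusion": report.confusion,
        "per_class": report.per_class,
        "oa": report.oa,
        "os": report.os,
        "op": report.op,
        "roc_points": report.roc_points,
        "pr_points": report.pr_points,
        "warnings": report.warnings,
    }
    json_path = os.path.join(out_dir, f"{stem}.json")
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1)
    pd.DataFrame(
        report.confusion, index=report.class_names, columns=report.class_names
    ).to_csv(os.path.join(out_dir, "confusion.csv"))
    for which, key in (("roc_points", "roc_points.csv"), ("pr_points", "pr_points.csv")):
        rows = []
        for name, pts in getattr(report, which).items():
            cols = list(pts.keys())
            for vals in zip(*pts.values()):
                rows.append({"class": name, **dict(zip(cols, vals))})
        pd.DataFrame(rows).to_csv(os.path.join(out_dir, key), index=False)
    return json_path


def read_report(json_path):
    """Round-trip counterpart of :func:`write_report`."""
    with open(json_path) as fh:
        payload = json.load(fh)
    return MetricsReport(
        class_names=tuple(payload["class_names"]),
        confusion=payload["confusion"],
        per_class=payload["per_class"],
        oa=payload["oa"],
        os=payload["os"],
        op=payload["op"],
        roc_points=payload["roc_points"],
        pr_points=payload["pr_points"],
        warnings=payload["warnings"],
    )
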