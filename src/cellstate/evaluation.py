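"""Confusion matrix, the accuracy/precision/recall/F1 battery, and OvR ROC.

Per-class precision, recall, and F1 come from a one-vs-rest marginalization
of the confusion matrix (TP on the diagonal, FN across the row, FP down the
column, TN everywhere else).  Headline values are macro averages —
unweighted means over classes — which is the informative choice on a
severely imbalanced task; micro averaging would collapse recall onto
accuracy.  Ratios that are 0/0 (a class never predicted, or absent from the
evaluated cells) are reported as 0 and flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C counts; rows are true classes, columns are predicted classes."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        C = len(self.classes)
        if counts.shape != (C, C) or np.any(counts < 0):
            raise ValueError("counts must be a C x C non-negative integer matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(
    true: Sequence[str], pred: Sequence[str], classes: Sequence[str] | None = None
) -> ConfusionMatrix:
    """Count (true, predicted) pairs. Labels outside ``classes`` are an error."""
    true = list(true)
    pred = list(pred)
    if len(true) != len(pred):
        raise ValueError(f"length mismatch: {len(true)} true vs {len(pred)} predicted")
    if classes is None:
        classes = sorted(set(true) | set(pred))
    known = set(classes)
    unknown = sorted((set(true) | set(pred)) - known)
    if unknown:
        raise ValueError(f"labels not in classes: {unknown}")
    counts = _sk_confusion(true, pred, labels=list(classes))
    return ConfusionMatrix(tuple(classes), counts)


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy plus per-class and macro precision/recall/F1.

    ``undefined`` lists (class, metric) pairs whose ratio was 0/0 and was
    reported as 0 by convention.
    """

    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: ConfusionMatrix
    auc: dict[str, float] = field(default_factory=dict)
    undefined: tuple[tuple[str, str], ...] = ()

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": {
                c: {
                    "precision": self.precision[c],
                    "recall": self.recall[c],
                    "f1": self.f1[c],
                    **({"auc": self.auc[c]} if c in self.auc else {}),
                }
                for c in self.confusion.classes
            },
            "undefined": [list(u) for u in self.undefined],
            "classes": list(self.confusion.classes),
            "confusion_counts": self.confusion.counts.tolist(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "class": c,
                "precision": self.precision[c],
                "recall": self.recall[c],
                "f1": self.f1[c],
                "auc": self.auc.get(c, np.nan),
            }
            for c in self.confusion.classes
        ]
        rows.append(
            {
                "class": "__macro__",
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
                "auc": np.nan,
            }
        )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _safe_ratio(num: float, den: float, flag_key, flags: list) -> float:
    if den == 0:
        if num == 0:
            flags.append(flag_key)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix, f1_mode: str = "per_class") -> MetricsReport:
    """Compute the metric battery from a confusion matrix.

    ``f1_mode='per_class'`` (default) averages per-class F1 values (macro-F1);
    ``'from_macro'`` instead forms F1 from the macro precision and recall.
    """
    if cm.total < 1:
        raise ValueError("empty confusion matrix")
    if f1_mode not in ("per_class", "from_macro"):
        raise ValueError(f"unknown f1_mode {f1_mode!r}")
    counts = cm.counts.astype(np.float64)
    tp = np.diag(counts)
    fn = counts.sum(axis=1) - tp
    fp = counts.sum(axis=0) - tp
    flags: list[tuple[str, str]] = []
    precision, recall, f1 = {}, {}, {}
    for i, c in enumerate(cm.classes):
        precision[c] = _safe_ratio(tp[i], tp[i] + fp[i], (c, "precision"), flags)
        recall[c] = _safe_ratio(tp[i], tp[i] + fn[i], (c, "recall"), flags)
        pr, re = precision[c], recall[c]
        f1[c] = 2 * pr * re / (pr + re) if (pr + re) > 0 else 0.0
        if (pr + re) == 0:
            flags.append((c, "f1"))
    macro_p = float(np.mean(list(precision.values())))
    macro_r = float(np.mean(list(recall.values())))
    if f1_mode == "per_class":
        macro_f1 = float(np.mean(list(f1.values())))
    else:
        macro_f1 = 2 * macro_p * macro_r / (macro_p + macro_r) if macro_p + macro_r else 0.0
    return MetricsReport(
        accuracy=float(tp.sum() / cm.total),
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=macro_f1,
        confusion=cm,
        undefined=tuple(flags),
    )


@dataclass(frozen=True)
class RocResult:
    """One-vs-rest ROC sweep per class. AUC is NaN (and flagged) for classes
    absent from the evaluated cells."""

    classes: tuple[str, ...]
    fpr: dict[str, np.ndarray]
    tpr: dict[str, np.ndarray]
    thresholds: dict[str, np.ndarray]
    auc: dict[str, float]
    undefined: tuple[str, ...]

    def to_tsv(self, path: str | Path) -> None:
        frames = []
        for c in self.classes:
            if c in self.fpr:
                frames.append(
                    pd.DataFrame(
                        {"class": c, "fpr": self.fpr[c], "tpr": self.tpr[c]}
                    )
                )
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def roc_ovr(
    true: Sequence[str], proba: np.ndarray, classes: Sequence[str]
) -> RocResult:
    """One-vs-rest ROC curves and trapezoid AUC per class.

    ``proba`` columns follow ``classes`` order and rows must sum to 1.
    """
    true = np.asarray(list(true), dtype=object)
    proba = np.asarray(proba, dtype=np.float64)
    classes = tuple(classes)
    if proba.shape != (len(true), len(classes)):
        raise ValueError(f"proba shape {proba.shape} inconsistent with inputs")
    if not np.allclose(proba.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    fpr, tpr, thr, auc = {}, {}, {}, {}
    undefined = []
    for i, c in enumerate(classes):
        y = (true == c).astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            undefined.append(c)
            auc[c] = float("nan")
            continue
        f, t, th = _sk_roc_curve(y, proba[:, i], drop_intermediate=False)
        fpr[c], tpr[c], thr[c] = f, t, th
        auc[c] = float(np.trapezoid(t, f))
    return RocResult(classes, fpr, tpr, thr, auc, tuple(undefined))


def evaluate_predictions(
    true: Sequence[str],
    pred: Sequence[str],
    proba: np.ndarray | None = None,
    classes: Sequence[str] | None = None,
    f1_mode: str = "per_class",
) -> MetricsReport:
    """Confusion + metrics (+ per-class AUC when probabilities are given)."""
    if classes is None:
        classes = sorted(set(true) | set(pred))
    cm = confusion(true, pred, classes)
    report = metrics(cm, f1_mode=f1_mode)
    if proba is not None:
        roc = roc_ovr(true, proba, classes)
        object.__setattr__(report, "auc", dict(roc.auc))
    return report
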