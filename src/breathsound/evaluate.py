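"""Splitting, evaluation metrics and cohort-style summary statistics.

The binary view treats abnormal (VS or SS) as the positive class by
default — the clinically motivated choice for detecting airway problems
(flip with ``positive=...``).  Three-class evaluation reports total
accuracy and *accuracy in abnormal sounds*: the accuracy restricted to
samples whose true label is VS or SS, i.e. how well VS and SS are told
apart (a true-abnormal sample predicted NS counts as an error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .labels import ABNORMAL, BINARY_LABELS, NORMAL, to_binary, validate_labels

__all__ = [
    "SplitSpec",
    "MetricsReport",
    "split_train_test",
    "binary_metrics",
    "three_class_metrics",
    "roc_curve",
    "class_distribution",
    "per_patient_stats",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split settings (default 80/20, stratified)."""

    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")


def split_train_test(labels: Sequence, spec: SplitSpec | None = None):
    """Deterministic index split; returns ``(train_idx, test_idx)``.

    Stratified mode rounds ``n_class x train_fraction`` per class
    (half away from zero), so e.g. {60 NS, 20 VS, 20 SS} at 0.8 yields
    48/16/16 training items.  Every class needs >= 2 items.
    """
    spec = spec or SplitSpec()
    labels = np.asarray(labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    rng = np.random.default_rng(spec.seed)
    train_parts, test_parts = [], []
    if spec.stratified:
        for cls in pd.unique(labels):
            idx = np.flatnonzero(labels == cls)
            if len(idx) < 2:
                raise ValueError(
                    f"class {cls!r} has {len(idx)} item(s); stratified split needs >= 2"
                )
            idx = rng.permutation(idx)
            n_train = int(round_half_away(len(idx) * spec.train_fraction, 0))
            n_train = min(max(n_train, 1), len(idx) - 1)
            train_parts.append(idx[:n_train])
            test_parts.append(idx[n_train:])
    else:
        idx = rng.permutation(n)
        n_train = int(round_half_away(n * spec.train_fraction, 0))
        n_train = min(max(n_train, 1), n - 1)
        train_parts.append(idx[:n_train])
        test_parts.append(idx[n_train:])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.concatenate(test_parts))
    return train, test


def _collapse(labels: Sequence) -> np.ndarray:
    labels = np.asarray(labels)
    if set(map(str, labels)) <= set(BINARY_LABELS):
        return labels.astype(str)
    return np.asarray(to_binary(list(map(str, labels))))


def roc_curve(true_labels: Sequence, scores: Sequence, positive: str = ABNORMAL):
    """ROC staircase for the binary view; returns ``(points, auc)``.

    ``points`` is a list of (FPR, TPR) pairs from (0,0) to (1,1); the
    AUC is the trapezoidal area under the staircase (equal to the
    pairwise rank statistic with ties counted half).
    """
    y = _collapse(true_labels)
    scores = np.asarray(scores, dtype=float)
    if len(y) != len(scores):
        raise ValueError("labels and scores must have equal length")
    if len(set(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(y == positive, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


@dataclass
class MetricsReport:
    """Container for the binary and three-class evaluation results."""

    binary: dict = field(default_factory=dict)
    three_class: dict = field(default_factory=dict)
    binary_confusion: pd.DataFrame | None = None
    three_class_confusion: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"view": "binary", "metric": k, "value": v}
            for k, v in self.binary.items()
        ] + [
            {"view": "three_class", "metric": k, "value": v}
            for k, v in self.three_class.items()
        ]
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = ["Binary (normal vs abnormal):"]
        for k, v in self.binary.items():
            lines.append(f"  {k:12s} {'absent' if v is None else f'{v:.4f}'}")
        if self.three_class:
            lines.append("Three-class (NS/VS/SS):")
            for k, v in self.three_class.items():
                lines.append(f"  {k:22s} {'absent' if v is None else f'{v:.4f}'}")
        return "\n".join(lines)


def binary_metrics(
    true_labels: Sequence,
    predicted_labels: Sequence,
    scores: Sequence | None = None,
    positive: str = ABNORMAL,
) -> MetricsReport:
    """Accuracy, sensitivity, specificity, PPV, NPV and AUC.

    Labels may be three-class (collapsed internally) or already binary.
    Ratios with a zero denominator are reported as ``None`` (absent),
    never as 0.  AUC needs ``scores`` for the positive class.
    """
    y_true = _collapse(true_labels)
    y_pred = _collapse(predicted_labels)
    if len(y_true) != len(y_pred):
        raise ValueError("true and predicted label lengths differ")
    negative = NORMAL if positive == ABNORMAL else ABNORMAL
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred == negative)))
    tn = int(np.sum((y_true == negative) & (y_pred == negative)))
    fp = int(np.sum((y_true == negative) & (y_pred == positive)))

    def ratio(num, den):
        return num / den if den > 0 else None

    metrics = {
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "auc": None,
    }
    if scores is not None and len(set(y_true)) == 2:
        _, metrics["auc"] = roc_curve(y_true, scores, positive=positive)
    confusion = pd.DataFrame(
        [[tp, fn], [fp, tn]],
        index=pd.Index([positive, negative], name="true"),
        columns=pd.Index([positive, negative], name="predicted"),
    )
    return MetricsReport(binary=metrics, binary_confusion=confusion)


def three_class_metrics(true_labels: Sequence, predicted_labels: Sequence) -> MetricsReport:
    """Total accuracy plus accuracy in abnormal sounds (VS-vs-SS)."""
    y_true = validate_labels(list(map(str, true_labels)))
    y_pred = validate_labels(list(map(str, predicted_labels)))
    if len(y_true) != len(y_pred):
        raise ValueError("true and predicted label lengths differ")
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    total = float(np.mean(y_true == y_pred))
    abnormal = np.isin(y_true, ("VS", "SS"))
    acc_abn = (
        float(np.mean(y_true[abnormal] == y_pred[abnormal]))
        if np.any(abnormal)
        else None
    )
    order = ["NS", "VS", "SS"]
    confusion = pd.DataFrame(
        [[int(np.sum((y_true == t) & (y_pred == p))) for p in order] for t in order],
        index=pd.Index(order, name="true"),
        columns=pd.Index(order, name="predicted"),
    )
    return MetricsReport(
        three_class={"total_accuracy": total, "accuracy_in_abnormal": acc_abn},
        three_class_confusion=confusion,
    )


def class_distribution(labels: Sequence) -> pd.DataFrame:
    """Counts and percentages per class (1-decimal, half away from zero)."""
    labels = list(map(str, labels))
    if len(labels) == 0:
        raise ValueError("no labels given")
    counts = pd.Series(labels).value_counts()
    order = [c for c in ("NS", "VS", "SS") if c in counts.index]
    order += [c for c in counts.index if c not in order]
    counts = counts.reindex(order)
    total = int(counts.sum())
    pct = [round_half_away(100.0 * c / total, 1) for c in counts]
    return pd.DataFrame({"count": counts.astype(int), "percent": pct})


def per_patient_stats(per_patient_counts) -> pd.DataFrame:
    """Mean and sample SD of per-patient counts.

    Accepts a 1-D sequence (one number per patient) or a DataFrame /
    mapping with one column per class; a ``total`` row/column is added
    for tabular input.  SD is NaN when only one patient is given
    (``n == 1`` flags the case).
    """

    def stats(values) -> dict:
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError("no patients given")
        return {
            "n": int(v.size),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
        }

    if isinstance(per_patient_counts, dict):
        per_patient_counts = pd.DataFrame(per_patient_counts)
    if isinstance(per_patient_counts, pd.DataFrame):
        if per_patient_counts.empty:
            raise ValueError("no patients given")
        rows = {col: stats(per_patient_counts[col]) for col in per_patient_counts}
        rows["total"] = stats(per_patient_counts.sum(axis=1))
        return pd.DataFrame(rows).T
    return pd.DataFrame({"value": stats(per_patient_counts)}).T
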