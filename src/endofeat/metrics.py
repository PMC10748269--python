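"""Classification metrics for bleeding detection, including ROC operating points.

Evaluation of a frame classifier uses the standard confusion-matrix metrics
at the 0.5 threshold (score >= threshold counts as blood), the ROC AUC, the
F1/F2 scores, and two families of operating points:

* high-specificity points ``sens@f`` — the sensitivity attained at the
  classification threshold whose false-positive rate is at most ``f``
  (f = 0.01, 0.001, 0.0001);
* high-sensitivity points ``spec@s`` — the specificity attained at the
  threshold whose sensitivity is at least ``s`` (s = 0.95, 0.99, 0.999).

Operating-point attainment is conservative: the achieved FPR never exceeds
the requested one and the achieved sensitivity never falls below the
requested one; no interpolation between thresholds is performed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .primitives import InvalidInputError

__all__ = [
    "METRIC_NAMES",
    "confusion",
    "f_beta",
    "roc_auc",
    "sens_at_fpr",
    "spec_at_sens",
    "full_report",
]

METRIC_NAMES = (
    "ROCAUC",
    "F1",
    "F2",
    "sensitivity",
    "specificity",
    "precision",
    "accuracy",
    "sens@0.01",
    "sens@0.001",
    "sens@0.0001",
    "spec@0.95",
    "spec@0.99",
    "spec@0.999",
)


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.ndim != 1 or labels.shape != scores.shape:
        raise InvalidInputError("scores and labels must be equal-length 1-D sequences")
    if scores.size == 0:
        raise InvalidInputError("empty score set")
    if scores.min() < 0 or scores.max() > 1:
        raise InvalidInputError("scores must lie in [0, 1]")
    if not np.all(np.isin(labels, (0, 1))):
        raise InvalidInputError("labels must be 0 (non-blood) or 1 (blood)")
    return scores, labels.astype(np.int64)


def _require_both_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise InvalidInputError("metric undefined: only one class present")


def confusion(scores, labels, threshold: float = 0.5) -> tuple[int, int, int, int]:
    """Confusion counts (TP, FP, TN, FN); score >= threshold predicts blood."""
    scores, labels = _validate(scores, labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, fp, tn, fn


def f_beta(precision: float, recall: float, beta: float) -> float:
    """F-score: (1 + b^2) P R / (b^2 P + R); 0 by convention when P = R = 0."""
    if precision == 0.0 and recall == 0.0:
        return 0.0
    b2 = beta * beta
    return (1.0 + b2) * precision * recall / (b2 * precision + recall)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (trapezoidal; ties handled probabilistically)."""
    scores, labels = _validate(scores, labels)
    _require_both_classes(labels)
    return float(roc_auc_score(labels, scores))


def sens_at_fpr(scores, labels, fpr: float) -> float:
    """Sensitivity at the loosest threshold whose false-positive rate is <= fpr."""
    if not 0.0 < fpr < 1.0:
        raise InvalidInputError("fpr must lie strictly between 0 and 1")
    scores, labels = _validate(scores, labels)
    _require_both_classes(labels)
    n_neg = int(np.sum(labels == 0))
    if n_neg < 1.0 / fpr:
        warnings.warn(
            f"only {n_neg} negatives: FPR resolution 1/{n_neg} is coarser than "
            f"the requested operating point {fpr}",
            stacklevel=2,
        )
    fprs, tprs, _ = roc_curve(labels, scores)
    ok = fprs <= fpr
    return float(tprs[ok].max()) if ok.any() else 0.0


def spec_at_sens(scores, labels, sens: float) -> float:
    """Specificity at the tightest threshold whose sensitivity is >= sens."""
    if not 0.0 < sens <= 1.0:
        raise InvalidInputError("sens must lie in (0, 1]")
    scores, labels = _validate(scores, labels)
    _require_both_classes(labels)
    fprs, tprs, _ = roc_curve(labels, scores)
    ok = tprs >= sens
    if not ok.any():
        return 0.0
    return float(1.0 - fprs[ok].min())


def full_report(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """All evaluation metrics; threshold-based metrics at the given threshold."""
    scores, labels = _validate(scores, labels)
    _require_both_classes(labels)
    tp, fp, tn, fn = confusion(scores, labels, threshold)
    n = tp + fp + tn + fn
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    report = {
        "ROCAUC": roc_auc(scores, labels),
        "F1": f_beta(precision, sensitivity, 1.0),
        "F2": f_beta(precision, sensitivity, 2.0),
        "sensitivity": sensitivity,
        "specificity": specificity,
        "precision": precision,
        "accuracy": (tp + tn) / n,
        "sens@0.01": sens_at_fpr(scores, labels, 0.01),
        "sens@0.001": sens_at_fpr(scores, labels, 0.001),
        "sens@0.0001": sens_at_fpr(scores, labels, 0.0001),
        "spec@0.95": spec_at_sens(scores, labels, 0.95),
        "spec@0.99": spec_at_sens(scores, labels, 0.99),
        "spec@0.999": spec_at_sens(scores, labels, 0.999),
    }
    assert tuple(report) == METRIC_NAMES
    return report


def read_scores_csv(path) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Read an image_id,score,label CSV into validated score/label arrays."""
    table = pd.read_csv(path)
    missing = {"score", "label"} - set(table.columns)
    if missing:
        raise InvalidInputError(f"scores CSV missing columns: {sorted(missing)}")
    scores, labels = _validate(table["score"].to_numpy(), table["label"].to_numpy())
    return scores, labels, table
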