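"""Classification metrics and the per-protein evaluation protocol.

Four metrics are reported: PR AUC and ROC AUC on raw probabilities, and F1
and MCC on predictions binarized at a 0.5 threshold (ties count positive).
Every metric is computed per complex and then averaged unweighted across
complexes, never pooled over residues.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import AlignmentError, EvaluationError, UndefinedMetricError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def binarize(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Label 1 iff p >= threshold."""
    p = np.asarray(probabilities, dtype=float)
    return (p >= threshold).astype(int)


def confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    y = np.asarray(labels, dtype=int)
    yhat = np.asarray(predictions, dtype=int)
    if y.shape != yhat.shape:
        raise AlignmentError("labels and predictions must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (yhat == 1))),
        fp=int(np.sum((y == 0) & (yhat == 1))),
        tn=int(np.sum((y == 0) & (yhat == 0))),
        fn=int(np.sum((y == 1) & (yhat == 0))),
    )


def f1(counts: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 on a degenerate denominator."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        warnings.warn("F1 undefined (no positives anywhere); returning 0")
        return 0.0
    return 2 * counts.tp / denom


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 on a degenerate denominator."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        warnings.warn("MCC undefined (degenerate margin); returning 0")
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(float(denom))


def _check_both_classes(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels, dtype=int)
    if y.size == 0 or y.min() == y.max():
        raise UndefinedMetricError(
            "AUC metrics require both classes to be present"
        )
    return y


def pr_auc(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Area under the precision-recall curve by step summation
    (average-precision), which avoids optimistic linear interpolation."""
    y = _check_both_classes(labels)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise AlignmentError("labels and probabilities must have equal length")
    return float(average_precision_score(y, p))


def roc_auc(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Trapezoidal ROC AUC, equal to the Mann-Whitney concordance
    probability."""
    y = _check_both_classes(labels)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise AlignmentError("labels and probabilities must have equal length")
    return float(roc_auc_score(y, p))


@dataclass
class MetricsReport:
    per_complex: pd.DataFrame  # columns: id, pr_auc, roc_auc, f1, mcc
    means: dict[str, float]
    threshold: float
    n_excluded: int  # complexes skipped for AUCs (single-class labels)


def evaluate_dataset(
    tracks: Sequence[tuple[np.ndarray, np.ndarray]],
    threshold: float = 0.5,
    ids: Sequence[str] | None = None,
) -> MetricsReport:
    """Per-complex metrics and their unweighted means.

    ``tracks`` is a list of (labels, probabilities) pairs, one per complex.
    Complexes whose labels contain a single class are excluded from the AUC
    averages (their F1/MCC are still scored) and counted in the report.
    """
    if not tracks:
        raise EvaluationError("no complexes to evaluate")
    if ids is None:
        ids = [f"complex_{i}" for i in range(len(tracks))]

    rows = []
    n_excluded = 0
    for cid, (labels, probs) in zip(ids, tracks):
        labels = np.asarray(labels, dtype=int)
        probs = np.asarray(probs, dtype=float)
        counts = confusion(labels, binarize(probs, threshold))
        row = {"id": cid, "f1": f1(counts), "mcc": mcc(counts)}
        try:
            row["pr_auc"] = pr_auc(labels, probs)
            row["roc_auc"] = roc_auc(labels, probs)
        except UndefinedMetricError:
            n_excluded += 1
            row["pr_auc"] = np.nan
            row["roc_auc"] = np.nan
            logger.info("complex %s excluded from AUC averaging (one class)", cid)
        rows.append(row)

    per_complex = pd.DataFrame(rows, columns=["id", "pr_auc", "roc_auc", "f1", "mcc"])
    means = {
        m: float(per_complex[m].mean(skipna=True))
        for m in ("pr_auc", "roc_auc", "f1", "mcc")
    }
    return MetricsReport(
        per_complex=per_complex,
        means=means,
        threshold=threshold,
        n_excluded=n_excluded,
    )
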