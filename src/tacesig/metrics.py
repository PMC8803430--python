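"""Binary-classification metrics used across model comparison.

Positive class is nonresponse (label 1) throughout. AUC uses the rank
(Mann–Whitney) formulation with half credit for tied scores; confusion
metrics derive from a single confusion matrix per evaluation, with PPV/NPV
reported as missing (None) when their denominator is empty rather than
coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy import stats

__all__ = ["MetricsRow", "auc_score", "compute_metrics", "metrics_from_predictions"]


@dataclass
class MetricsRow:
    auc: float
    f1: float
    accuracy: float
    youden: float
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def auc_score(y_true, score) -> float:
    """Area under the ROC curve by rank statistic, 0.5 credit per tied pair."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(score, dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: y_true contains a single class")
    r = stats.rankdata(s, method="average")
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def youden_index(sensitivity: float, specificity: float) -> float:
    """Youden's J statistic: sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


def _confusion(y: np.ndarray, pred: np.ndarray) -> MetricsRow:
    tp = int(((y == 1) & (pred == 1)).sum())
    tn = int(((y == 0) & (pred == 0)).sum())
    fp = int(((y == 0) & (pred == 1)).sum())
    fn = int(((y == 1) & (pred == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else None
    npv = tn / (tn + fn) if tn + fn else None
    acc = (tp + tn) / len(y)
    if ppv is not None and ppv + sens > 0:
        f1 = 2.0 * ppv * sens / (ppv + sens)
    else:
        f1 = 0.0
    return MetricsRow(
        auc=float("nan"),
        f1=f1,
        accuracy=acc,
        youden=youden_index(sens, spec),
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
    )


def compute_metrics(y_true, score, threshold: float = 0.5) -> MetricsRow:
    """Full metrics row from continuous scores thresholded at ``threshold``.

    A call is positive (nonresponse) when ``score > threshold``.
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(score, dtype=float)
    row = _confusion(y, (s > threshold).astype(int))
    row.auc = auc_score(y, s)
    return row


def metrics_from_predictions(y_true, score, y_pred) -> MetricsRow:
    """Metrics when the classifier supplies its own class calls.

    Used for model families whose continuous output is a margin rather than
    a probability, where thresholding the score at 0.5 would be wrong.
    """
    y = np.asarray(y_true, dtype=int)
    row = _confusion(y, np.asarray(y_pred, dtype=int))
    row.auc = auc_score(y, np.asarray(score, dtype=float))
    return row
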