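"""Regression and classification metrics with per-fold aggregation.

Regression tasks are scored by RMSE and MAE; classification tasks by
AUROC (equal to the Mann-Whitney statistic, ties contributing one half)
and AUPRC (area under the precision-recall step curve, no
interpolation). Reported values are always computed at molecule level —
after the scores of a molecule's augmented variants have been averaged —
never at augmented-record level.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    mean_absolute_error,
    mean_squared_error,
    roc_auc_score,
)

from .errors import SmilesAugError


def _check_pair(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if y_true.size == 0:
        raise SmilesAugError("metric called on empty input")
    if y_true.shape != y_pred.shape:
        raise SmilesAugError(
            f"length mismatch: {y_true.size} targets vs {y_pred.size} predictions"
        )
    return y_true, y_pred


def rmse(y_true, y_pred) -> float:
    """Root mean squared error."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    return float(np.sqrt(mean_squared_error(y_true, y_pred)))


def mae(y_true, y_pred) -> float:
    """Mean absolute error."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    return float(mean_absolute_error(y_true, y_pred))


def auroc(y_true, scores) -> float:
    """Area under the ROC curve, i.e. P(score+ > score-) + 0.5 P(tie).

    Raises on single-class input rather than silently returning 0.5.
    """
    y_true, scores = _check_pair(y_true, scores)
    if np.unique(y_true).size < 2:
        raise SmilesAugError("AUROC undefined: only one class present")
    return float(roc_auc_score(y_true, scores))


def auprc(y_true, scores) -> float:
    """Area under the precision-recall step curve (average precision)."""
    y_true, scores = _check_pair(y_true, scores)
    if (y_true == 1).sum() == 0:
        raise SmilesAugError("AUPRC undefined: no positive examples")
    return float(average_precision_score(y_true, scores))


def compute_metrics(y_true, scores, task: str) -> dict[str, float]:
    """Task-appropriate metric map, ignoring molecules with missing labels.

    For classification, a fold whose test molecules are all one class
    yields NaN metrics (recorded, not raised, so a CV run can finish).
    """
    y_true = np.asarray(y_true, dtype=np.float64).ravel()
    scores = np.asarray(scores, dtype=np.float64).ravel()
    observed = ~np.isnan(y_true)
    y_true, scores = y_true[observed], scores[observed]
    if task == "regression":
        return {"rmse": rmse(y_true, scores), "mae": mae(y_true, scores)}
    try:
        return {"auroc": auroc(y_true, scores), "auprc": auprc(y_true, scores)}
    except SmilesAugError:
        return {"auroc": float("nan"), "auprc": float("nan")}


@dataclass(frozen=True)
class FoldResult:
    """Metric values for one cross-validation fold."""

    fold_index: int
    metrics: dict[str, float]
    n_test_molecules: int


@dataclass(frozen=True)
class EvalReport:
    """Per-fold values plus their mean and standard deviation."""

    per_fold: list[FoldResult]
    mean: dict[str, float]
    std: dict[str, float]
    config_fingerprint: str = ""

    def to_dict(self) -> dict:
        return {
            "per_fold": [
                {
                    "fold_index": f.fold_index,
                    "metrics": f.metrics,
                    "n_test_molecules": f.n_test_molecules,
                }
                for f in self.per_fold
            ],
            "mean": self.mean,
            "std": self.std,
            "config_fingerprint": self.config_fingerprint,
        }


def fingerprint(config: object) -> str:
    """Short stable hash of any JSON-serializable configuration."""
    text = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def summarize(per_fold: list[FoldResult], config_fingerprint: str = "") -> EvalReport:
    """Mean and (population) standard deviation of each metric over folds."""
    if not per_fold:
        raise SmilesAugError("summarize called with no folds")
    keys = set(per_fold[0].metrics)
    for fold in per_fold[1:]:
        if set(fold.metrics) != keys:
            raise SmilesAugError("inconsistent metric keys across folds")
    mean = {
        k: float(np.mean([f.metrics[k] for f in per_fold])) for k in sorted(keys)
    }
    std = {
        k: float(np.std([f.metrics[k] for f in per_fold])) for k in sorted(keys)
    }
    return EvalReport(per_fold=list(per_fold), mean=mean, std=std,
                      config_fingerprint=config_fingerprint)
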