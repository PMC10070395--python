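"""Evaluation metrics and the masked multi-task training loss."""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import rankdata

from .autodiff import Tensor, as_tensor

logger = logging.getLogger(__name__)

__all__ = ["roc_auc", "rmse", "masked_loss", "UndefinedMetricError"]


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined (e.g. single-class ROC-AUC)."""


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve as the Mann-Whitney pair statistic:
    (concordant pairs + 0.5 * tied pairs) / (positives * negatives)."""
    labels = np.asarray(labels, dtype=np.float64)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC-AUC undefined: labels contain a single class")
    ranks = rankdata(scores)  # average ranks handle ties as half-concordant
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def rmse(pred, truth) -> float:
    """Root-mean-square error."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def masked_loss(predictions, labels, mask, task_type: str):
    """Mean loss over observed entries of a molecules x tasks batch.

    Classification: binary cross-entropy on raw scores (stable softplus
    form); regression: mean squared error. A fully-masked batch contributes
    zero with a warning. Returns a scalar :class:`Tensor` when
    ``predictions`` is a Tensor (differentiable), else a float.
    """
    is_tensor = isinstance(predictions, Tensor)
    pred = as_tensor(predictions)
    labels = np.asarray(labels, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if pred.shape != labels.shape or pred.shape != mask.shape:
        raise ValueError("predictions, labels and mask must share one shape")
    count = int(mask.sum())
    if count == 0:
        logger.warning("fully-masked batch: loss contribution is zero")
        return Tensor(0.0) if is_tensor else 0.0
    m = Tensor(mask.astype(np.float64))
    y = Tensor(np.where(mask, labels, 0.0))
    if task_type == "classification":
        elem = pred.softplus() - pred * y  # = BCE-with-logits up to constants in y
    elif task_type == "regression":
        elem = (pred - y) ** 2
    else:
        raise ValueError(f"unknown task_type {task_type!r}")
    loss = (elem * m).sum() / float(count)
    return loss if is_tensor else float(loss.data)
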