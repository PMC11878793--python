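"""Evaluation metrics: ROC-AUC for classification, RMSE/MAE for regression.

Multi-task labels may be partially missing; masked entries are excluded.
A classification task that is single-class after masking is skipped with a
warning rather than contributing a silent NaN.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.metrics import mean_absolute_error, mean_squared_error, roc_auc_score

__all__ = ["compute_metrics"]


def compute_metrics(predictions, labels, mask=None, task_kind: str = "binary_classification") -> dict:
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=float)
    # 1-D inputs are a single task, not one sample of many tasks
    predictions = predictions.reshape(-1, 1) if predictions.ndim == 1 else predictions
    labels = labels.reshape(-1, 1) if labels.ndim == 1 else labels
    if predictions.shape != labels.shape:
        predictions = predictions.reshape(labels.shape)
    mask = np.ones_like(labels, dtype=bool) if mask is None else np.asarray(mask, dtype=bool).reshape(labels.shape)

    if task_kind == "binary_classification":
        per_task = []
        for j in range(labels.shape[1]):
            m = mask[:, j]
            y, p = labels[m, j], predictions[m, j]
            if y.size == 0 or len(np.unique(y)) < 2:
                warnings.warn(
                    f"task {j}: single class after masking; skipped in ROC-AUC",
                    stacklevel=2,
                )
                continue
            per_task.append(roc_auc_score(y, p))
        if not per_task:
            raise ValueError("no task had both classes present after masking")
        return {"roc_auc": float(np.mean(per_task)), "per_task_roc_auc": per_task}

    if task_kind == "regression":
        m = mask.ravel()
        y, p = labels.ravel()[m], predictions.ravel()[m]
        return {
            "rmse": float(np.sqrt(mean_squared_error(y, p))),
            "mae": float(mean_absolute_error(y, p)),
        }

    raise ValueError(f"unknown task_kind {task_kind!r}")
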