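"""Evaluation metrics: pooled patient-hour AUROC, patient-level bootstrap
confidence intervals, and thresholded confusion metrics.

AUROC is pooled over all patient-hours ("averaged over all patients and
observation times"), not averaged per patient. Bootstrap resampling is done
at the patient level, respecting within-stay correlation, with percentile
intervals (100 resamples are too few for BCa stability).
"""

from __future__ import annotations

import logging
from typing import Callable, Optional

import numpy as np

logger = logging.getLogger(__name__)


def auroc(scores: np.ndarray, labels: np.ndarray) -> Optional[float]:
    """Probability that a random positive outscores a random negative (ties 1/2).

    Returns None (with a warning) when only one class is present.
    """
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        logger.warning("AUROC undefined: only one class present")
        return None
    return float(roc_auc_score(labels, scores))


def confusion_metrics(predictions: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """Sensitivity, specificity and accuracy of a binary prediction trace."""
    predictions = np.asarray(predictions).astype(bool)
    labels = np.asarray(labels).astype(bool)
    tp = int(np.sum(predictions & labels))
    fn = int(np.sum(~predictions & labels))
    tn = int(np.sum(~predictions & ~labels))
    fp = int(np.sum(predictions & ~labels))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / len(labels) if len(labels) else float("nan")
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc}


def bootstrap_ci(metric_fn: Callable[[np.ndarray, np.ndarray], Optional[float]],
                 scores: np.ndarray, labels: np.ndarray, stay_ids: np.ndarray,
                 n_resamples: int = 100, seed: int = 0,
                 level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI with the patient as the resampling unit.

    Patients are drawn with replacement; the metric is recomputed on the
    concatenated rows of the drawn patients. Resamples on which the metric
    is undefined are redrawn (count logged). Deterministic given the seed.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    stay_ids = np.asarray(stay_ids)
    unique_ids = np.unique(stay_ids)
    if len(unique_ids) < 2:
        raise ValueError("bootstrap requires at least 2 patients")
    rows_by_id = {sid: np.flatnonzero(stay_ids == sid) for sid in unique_ids}

    rng = np.random.default_rng(seed)
    values = []
    redraws = 0
    while len(values) < n_resamples:
        draw = rng.choice(unique_ids, size=len(unique_ids), replace=True)
        rows = np.concatenate([rows_by_id[sid] for sid in draw])
        value = metric_fn(scores[rows], labels[rows])
        if value is None or not np.isfinite(value):
            redraws += 1
            if redraws > 50 * n_resamples:
                raise ValueError("metric undefined on almost every bootstrap resample")
            continue
        values.append(value)
    if redraws:
        logger.info("bootstrap redrew %d degenerate resamples", redraws)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lower), float(upper)
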