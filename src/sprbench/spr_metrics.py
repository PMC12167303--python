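"""Confusion-matrix construction and phase-recognition performance metrics.

Three metrics summarise a rater's (or model's) answers against ground truth:

* **accuracy** — trace / total of the confusion matrix;
* **weighted F1** — per-class F1 averaged with weights proportional to each
  class's true support;
* **normalized L1/2 spread** — a dispersion statistic on the confusion
  matrix.  For a row-normalized probability vector ``p`` over ``k`` phases,
  the row statistic is ``(sum_i sqrt(p_i))**2``, which equals 1 for a
  one-hot row (all answers on one phase) and ``k`` for a uniform row
  (maximal spread).  Rows are averaged and the mean is rescaled to ``[0, 1]``
  via ``(mean - 1) / (k - 1)``, so 0 means perfectly concentrated answers
  and 1 means answers spread uniformly over the whole phase set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .workflow_model import PhaseSchema, ValidationError

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "confusion_matrix",
    "accuracy",
    "weighted_f1",
    "lhalf_row",
    "lhalf_spread",
    "metric_set",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """k x k count matrix; rows index the true phase, columns the answer."""

    schema: PhaseSchema
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        k = self.schema.k
        if counts.shape != (k, k):
            raise ValidationError(f"counts must be {k}x{k}, got {counts.shape}")
        if (counts < 0).any():
            raise ValidationError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricSet:
    """The three performance metrics plus the number of scored responses."""

    accuracy: float
    weighted_f1: float
    lhalf_normalized: float
    n: int


def confusion_matrix(
    truths: Sequence[str], answers: Sequence[str], schema: PhaseSchema
) -> ConfusionMatrix:
    """Count (true, answered) phase pairs into a k x k matrix."""
    if len(truths) != len(answers):
        raise ValidationError(
            f"length mismatch: {len(truths)} truths vs {len(answers)} answers"
        )
    counts = np.zeros((schema.k, schema.k), dtype=np.int64)
    for t, a in zip(truths, answers):
        counts[schema.index(t), schema.index(a)] += 1
    return ConfusionMatrix(schema, counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of answers on the diagonal."""
    if cm.total == 0:
        raise ValidationError("cannot score an empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def weighted_f1(cm: ConfusionMatrix) -> float:
    """Support-weighted mean of per-class F1 scores.

    A class's F1 is the harmonic mean of its precision and recall, taken as 0
    when precision + recall is 0; classes with zero true support carry zero
    weight.
    """
    if cm.total == 0:
        raise ValidationError("cannot score an empty confusion matrix")
    counts = cm.counts.astype(float)
    support = counts.sum(axis=1)
    predicted = counts.sum(axis=0)
    tp = np.diag(counts)
    f1 = np.zeros(cm.schema.k)
    denom = support + predicted  # = tp+fn + tp+fp
    np.divide(2.0 * tp, denom, out=f1, where=denom > 0)
    return float((f1 * support).sum() / support.sum())


def lhalf_row(p: Sequence[float]) -> float:
    """L1/2 spread of one probability vector: ``(sum sqrt(p_i))**2``.

    Bounded by 1 (one-hot) and ``len(p)`` (uniform).
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValidationError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"probabilities must sum to 1, got {p.sum()!r}")
    return float(np.sqrt(p).sum() ** 2)


def lhalf_spread(cm: ConfusionMatrix) -> float:
    """Row-averaged L1/2 spread of a confusion matrix, rescaled to [0, 1].

    Each row with positive support is normalized to probabilities and scored
    with :func:`lhalf_row`; rows with zero support (phases never asked) are
    excluded from the average and logged.  The mean row score in ``[1, k]``
    maps to ``(mean - 1) / (k - 1)``.
    """
    counts = cm.counts.astype(float)
    sums = counts.sum(axis=1)
    included = sums > 0
    if not included.any():
        raise ValidationError("all confusion-matrix rows are empty")
    n_excluded = int((~included).sum())
    if n_excluded:
        log.info("lhalf_spread: excluding %d zero-support rows", n_excluded)
    rows = counts[included] / sums[included, None]
    scores = [lhalf_row(r) for r in rows]
    return float((np.mean(scores) - 1.0) / (cm.schema.k - 1.0))


def metric_set(cm: ConfusionMatrix) -> MetricSet:
    """All three metrics of one confusion matrix."""
    return MetricSet(
        accuracy=accuracy(cm),
        weighted_f1=weighted_f1(cm),
        lhalf_normalized=lhalf_spread(cm),
        n=cm.total,
    )
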