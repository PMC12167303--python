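"""Paired and rank-based inference for survey scores.

The study design compares each participant's single-frame score with their
video-snippet score, one pair per participant, using the Wilcoxon signed-rank
test; the per-group p-values are then held to a Bonferroni-corrected
threshold alpha / m.  Spearman rank correlation probes monotone association
(accuracy vs confidence, accuracy vs perceived difficulty).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .workflow_model import ValidationError

__all__ = [
    "PairedSample",
    "TestResult",
    "BonferroniResult",
    "wilcoxon_signed_rank",
    "bonferroni",
    "spearman_rho",
]

#: sample-size bound below which the exact signed-rank null is used (no ties)
EXACT_N_MAX = 25


@dataclass(frozen=True)
class PairedSample:
    """Scores of the same units under two conditions (frames vs snippets)."""

    units: tuple[str, ...]
    a: tuple[float, ...]  # condition 1 (single frames)
    b: tuple[float, ...]  # condition 2 (video snippets)

    def __post_init__(self) -> None:
        if not (len(self.units) == len(self.a) == len(self.b)):
            raise ValidationError("units, a and b must have equal lengths")
        if len(self.units) < 1:
            raise ValidationError("need at least one pair")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_effective: int
    method: str  # 'exact' | 'normal-approximation' | 't-approximation'


@dataclass(frozen=True)
class BonferroniResult:
    threshold: float
    reject: tuple[bool, ...]
    m: int


def wilcoxon_signed_rank(pairs: PairedSample) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on ``b - a``.

    Zero differences are discarded (the classical rule); |differences| are
    ranked with average ranks for ties and the statistic is
    ``min(W+, W-)``.  The p-value is exact (full null distribution) when the
    effective sample size is at most 25 and there are no ties in |d|;
    otherwise the normal approximation with tie and continuity correction is
    used.
    """
    d = np.asarray(pairs.b, dtype=float) - np.asarray(pairs.a, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValidationError("test undefined: all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)
    has_ties = len(np.unique(np.abs(d))) < n
    if n <= EXACT_N_MAX and not has_ties:
        method = "exact"
        res = stats.wilcoxon(d, zero_method="wilcox", method="exact")
    else:
        method = "normal-approximation"
        res = stats.wilcoxon(d, zero_method="wilcox", correction=True, method="approx")
    return TestResult(
        statistic=statistic,
        p_value=float(min(res.pvalue, 1.0)),
        n_effective=n,
        method=method,
    )


def bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> BonferroniResult:
    """Reject each test iff its p-value is strictly below ``alpha / m``."""
    p_values = list(p_values)
    if not p_values:
        raise ValidationError("no p-values to correct")
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    for p in p_values:
        if not (0 < p <= 1):
            raise ValidationError(f"p-values must be in (0, 1], got {p}")
    m = len(p_values)
    threshold = alpha / m
    return BonferroniResult(
        threshold=threshold,
        reject=tuple(p < threshold for p in p_values),
        m=m,
    )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with a two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal lengths")
    if len(x) < 3:
        raise ValidationError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("rank correlation undefined for a constant argument")
    rho, p = stats.spearmanr(x, y)
    return TestResult(
        statistic=float(rho),
        p_value=float(min(p, 1.0)),
        n_effective=len(x),
        method="t-approximation",
    )
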