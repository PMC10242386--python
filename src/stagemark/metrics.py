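"""Confusion-matrix metrics and rank-based AUROC for the diagnosis task.

Cancer is the positive class throughout.  Percentages are kept at full
precision here; report writers round to two decimals (half-even).
Undefined ratios follow documented conventions (0 on an empty
denominator; F1 = 0 when precision + recall = 0; MCC = 0 on a zero
denominator) rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import ConfigurationError

POSITIVE = "cancer"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ConfigurationError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ConfigurationError("no samples evaluated")

    @classmethod
    def from_labels(cls, y_true, y_pred, positive: str = POSITIVE) -> "ConfusionCounts":
        t = np.asarray(y_true) == positive
        p = np.asarray(y_pred) == positive
        return cls(
            tp=int((t & p).sum()),
            fp=int((~t & p).sum()),
            tn=int((~t & ~p).sum()),
            fn=int((t & ~p).sum()),
        )


@dataclass(frozen=True)
class MetricsRecord:
    balanced_accuracy: float  # percent
    specificity: float        # percent
    precision: float          # percent
    recall: float             # percent
    f1: float                 # percent
    mcc: float                # in [-1, 1]
    auroc: float | None       # in [0, 1]; None when no scores were given


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def balanced_accuracy(recall_pct: float, specificity_pct: float) -> float:
    """Mean of sensitivity and specificity, both on the percent scale."""
    return (recall_pct + specificity_pct) / 2.0


def f1_score(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall (percent in, percent out)."""
    if precision_pct + recall_pct == 0:
        return 0.0
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


def matthews_corrcoef(c: ConfusionCounts) -> float:
    tp, fp, tn, fn = (float(v) for v in (c.tp, c.fp, c.tn, c.fn))
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if den == 0:
        return 0.0
    return (tp * tn - fp * fn) / den


def auroc(scores, labels, positive: str = POSITIVE) -> float:
    """Mann-Whitney AUROC: P(random positive outscores a random negative).

    Computed from rank sums with midranks for ties (a tie counts 1/2).
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels) == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ConfigurationError("AUROC undefined: one class absent")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def compute_metrics(c: ConfusionCounts, scores=None, labels=None) -> MetricsRecord:
    """All diagnosis metrics from counts, plus AUROC when scores are supplied."""
    recall = 100.0 * _ratio(c.tp, c.tp + c.fn)
    specificity = 100.0 * _ratio(c.tn, c.tn + c.fp)
    precision = 100.0 * _ratio(c.tp, c.tp + c.fp)
    return MetricsRecord(
        balanced_accuracy=balanced_accuracy(recall, specificity),
        specificity=specificity,
        precision=precision,
        recall=recall,
        f1=f1_score(precision, recall),
        mcc=matthews_corrcoef(c),
        auroc=auroc(scores, labels) if scores is not None else None,
    )
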