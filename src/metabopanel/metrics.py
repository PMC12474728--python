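"""Binary-classification metrics: confusion counts, sensitivity/specificity,
unweighted accuracy, and rank-based ROC AUC."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata

from .errors import DataError


@dataclass(frozen=True)
class MetricsReport:
    """Sensitivity, specificity, unweighted accuracy (all %), ROC AUC, and the
    confusion counts they derive from. Unweighted accuracy is the arithmetic
    mean of sensitivity and specificity (class-balanced accuracy)."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DataError("confusion counts must be non-negative")
        if self.tp + self.fn == 0 or self.tn + self.fp == 0:
            raise DataError("both classes must be present to compute metrics")
        if not (0.0 <= self.auc <= 1.0):
            raise DataError(f"AUC out of range: {self.auc}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def unweighted_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0

    def to_dict(self) -> dict:
        out = asdict(self)
        out.update(
            sensitivity=self.sensitivity,
            specificity=self.specificity,
            unweighted_accuracy=self.unweighted_accuracy,
            n=self.n,
        )
        return out


def roc_auc(scores, y_true) -> float:
    """Rank-sum AUC: probability a random positive's score exceeds a random
    negative's, ties counted 1/2. Equivalent to the Mann-Whitney U statistic
    normalized by n_pos · n_neg."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def report_from_predictions(y_true, y_pred, scores) -> MetricsReport:
    """Build a MetricsReport from boolean case indicators, predicted case
    indicators, and continuous case scores."""
    y = np.asarray(y_true, dtype=bool)
    p = np.asarray(y_pred, dtype=bool)
    return MetricsReport(
        tp=int((p & y).sum()),
        fp=int((p & ~y).sum()),
        tn=int((~p & ~y).sum()),
        fn=int((~p & y).sum()),
        auc=roc_auc(scores, y),
    )


def confusion_from_rates(sensitivity_pct: float, specificity_pct: float,
                         n_pos: int, n_neg: int, auc: float = 0.5) -> MetricsReport:
    """Reconstruct integer confusion counts from printed sensitivity and
    specificity percentages and the group sizes.

    The nearest integer counts must round back to the printed one-decimal
    percentages; otherwise the printed rates are inconsistent with the stated
    group sizes and an error is raised.
    """
    tp = round(sensitivity_pct / 100.0 * n_pos)
    tn = round(specificity_pct / 100.0 * n_neg)
    for printed, count, n in ((sensitivity_pct, tp, n_pos), (specificity_pct, tn, n_neg)):
        if abs(100.0 * count / n - printed) > 0.05 + 1e-9:
            raise DataError(
                f"printed rate {printed}% is not a count out of {n} to one decimal"
            )
    return MetricsReport(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn, auc=auc)
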