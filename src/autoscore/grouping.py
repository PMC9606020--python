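"""Tertile classification of per-sample scores into high/intermediate/low.

Cuts are the empirical 1/3 and 2/3 quantiles (linear interpolation between
order statistics), computed per cancer type so cancer-specific expression
baselines do not leak across cohorts. Boundary inclusion is closed on both
cuts, with "low" taking precedence when the two cuts coincide (all-equal
scores degenerate to everyone "low", with a warning).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger("autoscore")

LABELS = ("low", "intermediate", "high")


@dataclass
class GroupAssignment:
    """Per-sample tertile labels with the score cuts that produced them."""

    labels: pd.Series  # sample -> low / intermediate / high
    cut_low: float
    cut_high: float
    cancer_type: str = ""
    degenerate: bool = field(default=False)

    def samples(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]

    def counts(self) -> dict[str, int]:
        return {lab: int((self.labels == lab).sum()) for lab in LABELS}


def tertile_classify(scores: pd.Series, cancer_type: str = "") -> GroupAssignment:
    """Split a score vector at its empirical tertiles.

    score <= cut_low -> low; score >= cut_high -> high; else intermediate.
    """
    if len(scores) < 3:
        raise ValueError(f"need >= 3 samples to form tertiles, got {len(scores)}")
    arr = scores.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("scores must be finite")
    cut_low, cut_high = np.quantile(arr, [1 / 3, 2 / 3])
    degenerate = bool(cut_low == cut_high)
    if degenerate:
        warnings.warn(
            f"tertile cuts coincide at {cut_low:g}; boundary samples resolve low-before-high",
            RuntimeWarning,
            stacklevel=2,
        )
    labels = pd.Series("intermediate", index=scores.index, dtype=object)
    labels[arr <= cut_low] = "low"  # low takes precedence on coinciding cuts
    labels[(arr >= cut_high) & (labels != "low")] = "high"
    return GroupAssignment(
        labels=labels,
        cut_low=float(cut_low),
        cut_high=float(cut_high),
        cancer_type=cancer_type,
        degenerate=degenerate,
    )


def classify_by_cancer(scores: pd.Series, cancer_of: pd.Series) -> dict[str, GroupAssignment]:
    """Tertile-classify scores independently within each cancer type."""
    out: dict[str, GroupAssignment] = {}
    for cancer, idx in scores.groupby(cancer_of.reindex(scores.index)).groups.items():
        out[str(cancer)] = tertile_classify(scores.loc[idx], cancer_type=str(cancer))
    return out


def eligible_cancers(assignments: dict[str, GroupAssignment], min_n: int = 30) -> list[str]:
    """Cancers with at least ``min_n`` samples in BOTH the high and low groups."""
    keep = []
    for cancer, asg in assignments.items():
        counts = asg.counts()
        if counts["high"] >= min_n and counts["low"] >= min_n:
            keep.append(cancer)
        else:
            logger.info(
                "cancer %s excluded: high=%d low=%d (< %d)",
                cancer, counts["high"], counts["low"], min_n,
            )
    return keep


class TertileClassifier(BaseEstimator):
    """Estimator wrapper fixing tertile cuts on a reference score vector.

    ``fit`` learns cut_low_/cut_high_ from the training scores; ``predict``
    labels (possibly new) scores against the learned cuts with the same
    closed-boundary, low-precedence rule.
    """

    def fit(self, X, y=None) -> "TertileClassifier":
        scores = pd.Series(np.asarray(X, dtype=float).ravel())
        asg = tertile_classify(scores)
        self.cut_low_ = asg.cut_low
        self.cut_high_ = asg.cut_high
        self.degenerate_ = asg.degenerate
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "cut_low_"):
            raise ValueError("TertileClassifier is not fitted")
        arr = np.asarray(X, dtype=float).ravel()
        labels = np.full(arr.shape, "intermediate", dtype=object)
        labels[arr <= self.cut_low_] = "low"
        labels[(arr >= self.cut_high_) & (labels != "low")] = "high"
        return labels
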