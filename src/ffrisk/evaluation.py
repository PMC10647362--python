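"""Evaluation quantities for the group-split ensemble.

The headline metric is the *simulated accuracy*: the unweighted mean of the
retained base models' held-out accuracies.  It estimates the average
performance of the ensemble's parts, not a held-out accuracy of the full
voting classifier — with so few labeled patients no comprehensive test set
exists to measure the latter.  Per-held-out-size means break the same
quantity down by train/test split ratio, and feature importances are
aggregated as the per-feature mean of the members' (normalized,
mean-decrease-in-impurity) importances.

The high-risk F1 score is provided with an explicit degenerate path: a
held-out set containing no high-risk patient has an *undefined* F1, and
reporting it as 0 would silently drag down any aggregate — the reason
accuracy, not F1, is the primary metric here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import f1_score

from .cohort import HIGH
from .ensemble import EnsembleModel

__all__ = [
    "EvaluationReport",
    "simulated_accuracy",
    "per_split_accuracy",
    "aggregate_feature_importance",
    "f1_high_risk",
    "evaluate",
]


@dataclass
class EvaluationReport:
    """Summary of an ensemble: overall and per-split simulated accuracy,
    aggregated feature importances, and the lesion-feature aggregate
    (the mean importance of the observed coronary artery columns)."""

    simulated_accuracy: float
    per_split_accuracy: dict[int, float]
    feature_importance: dict[str, float]
    lesion_importance_mean: float
    member_count: int


def simulated_accuracy(ensemble: EnsembleModel) -> float:
    """Unweighted mean of all members' held-out accuracies."""
    if not ensemble.members:
        raise ValueError("empty ensemble")
    return float(np.mean([m.heldout_accuracy for m in ensemble.members]))


def per_split_accuracy(ensemble: EnsembleModel) -> dict[int, float]:
    """Mean held-out accuracy per held-out size.

    Sizes with no retained member are absent from the map, not zero; the
    count-weighted mean over the map equals :func:`simulated_accuracy`.
    """
    if not ensemble.members:
        raise ValueError("empty ensemble")
    acc: dict[int, list[float]] = {}
    for m in ensemble.members:
        acc.setdefault(m.configuration.heldout_size, []).append(m.heldout_accuracy)
    return {size: float(np.mean(v)) for size, v in sorted(acc.items())}


def aggregate_feature_importance(ensemble: EnsembleModel) -> dict[str, float]:
    """Per-feature unweighted mean of member importances.

    Member importances are normalized by the base learner, so the aggregate
    sums to 1 (up to members that are degenerately all-zero).  Invariant in
    member order.  Raises if members disagree on the feature space.
    """
    if not ensemble.members:
        raise ValueError("empty ensemble")
    keys = list(ensemble.members[0].feature_importances)
    for m in ensemble.members:
        if list(m.feature_importances) != keys:
            raise ValueError("members have inconsistent feature spaces")
    stacked = np.asarray(
        [[m.feature_importances[k] for k in keys] for m in ensemble.members]
    )
    means = stacked.mean(axis=0)
    return dict(zip(keys, means.tolist()))


def f1_high_risk(
    predicted: Sequence[str], truth: Sequence[str]
) -> float | None:
    """F1 score with the high-risk class as positive.

    Returns ``None`` (undefined, deliberately not 0) when the truth
    contains no high-risk sample: precision/recall have no positive support
    and a zero would bias any aggregation over many small test sets.
    """
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth lengths differ")
    if len(truth) == 0:
        raise ValueError("empty label lists")
    if HIGH not in truth:
        return None
    return float(f1_score(list(truth), list(predicted), pos_label=HIGH, zero_division=0.0))


def evaluate(ensemble: EnsembleModel) -> EvaluationReport:
    """Full evaluation report for one ensemble."""
    importance = aggregate_feature_importance(ensemble)
    lesions = [importance[n] for n in ensemble.lesion_feature_names if n in importance]
    return EvaluationReport(
        simulated_accuracy=simulated_accuracy(ensemble),
        per_split_accuracy=per_split_accuracy(ensemble),
        feature_importance=importance,
        lesion_importance_mean=float(np.mean(lesions)) if lesions else math.nan,
        member_count=len(ensemble.members),
    )
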