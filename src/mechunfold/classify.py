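"""Significance tests on rupture-force sets and tilt-based ROC classification.

Two systems differ significantly when the difference of mean rupture
forces exceeds twice the combined standard error, 2·√(ε1²+ε2²), at every
requested pulling velocity (a Z-test margin applied per velocity).

For pathway classification, the maximum tilt angle of a trajectory scores
whether its force profile shows three distinct peaks ("shearing", high
second-peak force) or lacks the middle peak ("tearing", low force); the
score quality is summarized as ROC AUC, which equals the Mann–Whitney
pair-ordering probability with ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .forces import (DEFAULT_MIN_SEPARATION, DEFAULT_PROMINENCE, SmoothedTrace,
                     count_peaks)

__all__ = ["MeanComparison", "RocCurve", "z_compare", "z_compare_multi",
           "roc", "label_high_low"]


@dataclass
class MeanComparison:
    """Z-test comparison of two rupture-force samples."""

    label_a: str
    label_b: str
    mean_a: float  # pN
    mean_b: float  # pN
    sem_a: float  # pN
    sem_b: float  # pN
    z_margin: float  # pN, 2·sqrt(sem_a² + sem_b²)
    significant: bool

    @classmethod
    def from_summary(cls, mean_a: float, sem_a: float, mean_b: float, sem_b: float,
                     label_a: str = "A", label_b: str = "B") -> "MeanComparison":
        margin = 2.0 * float(np.hypot(sem_a, sem_b))
        return cls(label_a=label_a, label_b=label_b, mean_a=mean_a, mean_b=mean_b,
                   sem_a=sem_a, sem_b=sem_b, z_margin=margin,
                   significant=abs(mean_a - mean_b) >= margin)


@dataclass
class RocCurve:
    """ROC of a score against a binary label."""

    scores: np.ndarray
    labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def _sem(x: np.ndarray) -> float:
    # standard error of the mean with the n-1 (sample) denominator
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def z_compare(a: Sequence[float], b: Sequence[float],
              label_a: str = "A", label_b: str = "B") -> MeanComparison:
    """Compare two force samples by the 2·√(ε1²+ε2²) margin rule."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    return MeanComparison.from_summary(
        float(a.mean()), _sem(a), float(b.mean()), _sem(b), label_a, label_b)


def z_compare_multi(
    samples_a: Mapping[float, Sequence[float]],
    samples_b: Mapping[float, Sequence[float]],
    velocities: Sequence[float],
    label_a: str = "A",
    label_b: str = "B",
) -> tuple[bool, dict[float, MeanComparison]]:
    """Per-velocity Z comparisons; overall verdict requires all to pass.

    Returns (significant at every requested velocity, per-velocity details).
    """
    per_velocity = {}
    for v in velocities:
        if v not in samples_a or v not in samples_b:
            raise KeyError(f"no samples at velocity {v} for both systems")
        per_velocity[v] = z_compare(samples_a[v], samples_b[v], label_a, label_b)
    return all(c.significant for c in per_velocity.values()), per_velocity


def roc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC curve and trapezoidal AUC from a threshold sweep over the scores.

    Labels are binary (1 = positive class, e.g. high second-peak force).
    The trapezoidal AUC equals the Mann–Whitney U statistic with ties
    counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels):
        raise ValueError("scores/labels length mismatch")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
    return RocCurve(scores=scores, labels=labels, fpr=fpr, tpr=tpr,
                    thresholds=thresholds, auc=float(_sk_auc(fpr, tpr)))


def label_high_low(
    traces: Sequence[SmoothedTrace],
    prominence: float = DEFAULT_PROMINENCE,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    n_peaks_high: int = 3,
) -> np.ndarray:
    """Binary labels from the peak structure of smoothed force profiles.

    1 ("high") when the full profile shows at least ``n_peaks_high`` peaks
    at the configured prominence/separation, 0 ("low", missing middle peak)
    otherwise.
    """
    labels = [int(count_peaks(st, prominence, min_separation)[0] >= n_peaks_high)
              for st in traces]
    return np.asarray(labels, dtype=int)
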