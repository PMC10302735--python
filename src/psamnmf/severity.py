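"""Trunk-displacement severity labeling and evaluation against FMA-UE.

Stroke survivors compensate for impaired arm function with trunk motion, so
per-cluster mean trunk displacement orders clusters by severity: the cluster
with the lowest mean displacement is the least severe.  Ground truth comes
from the clinician-scored FMA-UE (0-66, lower = more impaired), banded into
k ordered severity classes.  Metrics are class-support-weighted accuracy,
precision, recall and F-score (weighted recall equals accuracy identically).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .baseline_ensemble import Partition
from .motion_io import FMA_MAX, MotionTrial, ValidationError
from .preprocessing import ScalarSeries

BASELINE_SAMPLES = 10  # per-axis baseline = mean of the first 10 samples

#: Ordered class names, least to most severe, per k.
CLASS_NAMES = {2: ("non-severe", "severe"), 3: ("non-severe", "mild", "severe")}

#: Default FMA-UE band edges: < 29 severe; k=3 adds [29, 43) mild.
DEFAULT_THRESHOLDS = {2: (29,), 3: (29, 43)}


@dataclass
class TrunkDisplacement:
    """Per-step trunk displacement of one trial, and its time average."""

    series: ScalarSeries
    trial_mean: float
    components: np.ndarray  # (T, 3) averaged per-axis displacement


@dataclass
class SeverityLabeling:
    """Map cluster id -> severity class, ranked by mean trunk displacement."""

    cluster_to_class: dict[int, str]
    cluster_means: dict[int, float]

    def apply(self, p: Partition) -> np.ndarray:
        return np.array([self.cluster_to_class[c] for c in p.labels])


@dataclass
class MetricsReport:
    """Class-weighted classification metrics against FMA-derived truth."""

    accuracy: float
    precision: float
    recall: float
    f_score: float
    confusion: np.ndarray
    classes: tuple[str, ...]


def trunk_displacement(trial: MotionTrial, signed_sum: bool = False) -> TrunkDisplacement:
    """Per-step trunk displacement relative to a 10-sample baseline.

    Per trunk channel, the mean of the first 10 samples is subtracted per
    axis and the per-axis displacements are combined into one value per
    step: |TD_x| + |TD_y| + |TD_z| (set ``signed_sum`` for the literal
    signed sum, which cancels for oscillatory sway).  With several trunk
    markers (camera profile) the per-marker series are averaged.
    """
    td_per_channel = []
    comp_per_channel = []
    for name in trial.trunk_channels:
        if name not in trial.channels:
            raise ValidationError(f"trunk channel {name!r} missing")
        series = trial.channels[name]
        if series.shape[0] < BASELINE_SAMPLES:
            raise ValidationError(
                f"trunk channel {name!r} shorter than the {BASELINE_SAMPLES}-sample baseline"
            )
        baseline = series[:BASELINE_SAMPLES].mean(axis=0)
        delta = series - baseline
        comp = delta if signed_sum else np.abs(delta)
        td_per_channel.append(comp.sum(axis=1))
        comp_per_channel.append(comp)
    td = np.mean(td_per_channel, axis=0)
    components = np.mean(comp_per_channel, axis=0)
    return TrunkDisplacement(
        series=ScalarSeries(td, "trunk_displacement", trial.sampling_rate),
        trial_mean=float(td.mean()),
        components=components,
    )


def label_clusters(p: Partition, td_means: np.ndarray, k: int) -> SeverityLabeling:
    """Rank clusters by mean trunk displacement; highest mean = most severe.

    ``td_means`` holds the per-instance trial-mean displacement, aligned
    with the partition.  Ties in cluster means rank the lower cluster id as
    less severe.  An empty cluster is an error.
    """
    td_means = np.asarray(td_means, dtype=float)
    if td_means.shape[0] != p.n:
        raise ValidationError("td_means misaligned with partition")
    names = CLASS_NAMES[k]
    cluster_means = {}
    for c in range(k):
        members = p.labels == c
        if not members.any():
            raise ValidationError(f"cluster {c} is empty; cannot rank severity")
        cluster_means[c] = float(td_means[members].mean())
    order = sorted(cluster_means, key=lambda c: (cluster_means[c], c))
    mapping = {c: names[rank] for rank, c in enumerate(order)}
    return SeverityLabeling(cluster_to_class=mapping, cluster_means=cluster_means)


def fma_to_severity(
    fma_ue: int, k: int, thresholds: tuple[int, ...] | None = None
) -> str:
    """Band an FMA-UE score into one of k ordered severity classes.

    Defaults: severe iff score < 29; for k=3, [29, 43) is mild and [43, 66]
    non-severe (half-open bands, boundary scores fall in the milder class).
    """
    if not 0 <= fma_ue <= FMA_MAX:
        raise ValidationError(f"FMA-UE score {fma_ue} outside [0, {FMA_MAX}]")
    thresholds = thresholds if thresholds is not None else DEFAULT_THRESHOLDS[k]
    if len(thresholds) != k - 1 or list(thresholds) != sorted(thresholds):
        raise ValidationError("need k-1 increasing thresholds")
    names = CLASS_NAMES[k]
    if k == 2:
        return names[1] if fma_ue < thresholds[0] else names[0]
    severe_edge, mild_edge = thresholds
    if fma_ue < severe_edge:
        return "severe"
    if fma_ue < mild_edge:
        return "mild"
    return "non-severe"


def evaluate(pred, truth) -> MetricsReport:
    """Class-weighted accuracy / precision / recall / F-score + confusion.

    Per-class precision, recall and F1 are combined with class-support
    weights, which makes weighted recall identical to accuracy.  Classes
    predicted but absent from the truth score 0 (zero-division convention).
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValidationError("pred and truth differ in length")
    classes = tuple(sorted(set(truth.tolist()) | set(pred.tolist())))
    cm = _sk_confusion(truth, pred, labels=list(classes))
    accuracy = float(np.trace(cm)) / float(cm.sum())
    precision, recall, f_score, _ = precision_recall_fscore_support(
        truth, pred, labels=list(classes), average="weighted", zero_division=0
    )
    return MetricsReport(
        accuracy=accuracy,
        precision=float(precision),
        recall=float(recall),
        f_score=float(f_score),
        confusion=cm,
        classes=classes,
    )


def severity_truth_for_trials(records, k: int, thresholds=None) -> np.ndarray:
    """Per-trial ground-truth class: each trial inherits its subject's band."""
    from .motion_io import all_trials

    by_subject = {
        r.subject_id: fma_to_severity(r.fma_ue, k, thresholds) for r in records
    }
    return np.array([by_subject[t.subject_id] for t in all_trials(records)])


def trunk_means_for_trials(records, signed_sum: bool = False) -> np.ndarray:
    """Per-trial mean trunk displacement, in cohort instance order."""
    from .motion_io import all_trials

    return np.array(
        [trunk_displacement(t, signed_sum).trial_mean for t in all_trials(records)]
    )


__all__ = [
    "BASELINE_SAMPLES", "CLASS_NAMES", "DEFAULT_THRESHOLDS",
    "TrunkDisplacement", "SeverityLabeling", "MetricsReport",
    "trunk_displacement", "label_clusters", "fma_to_severity", "evaluate",
    "severity_truth_for_trials", "trunk_means_for_trials",
]
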