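"""Annotation-performance validation against spiked ground truth.

Confusion counting follows the workflow's own convention, which differs
from the textbook confusion matrix: a feature annotated with the wrong
structure counts toward BOTH the false negatives (it was not correctly
annotated) and the false positives (a wrong structure was asserted), while
an unannotated feature is a false negative only. Under this convention
TP + FN equals the evaluable universe, so TPR is "fraction of evaluable
features correctly annotated" and precision is "fraction of asserted
structures that are correct".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional

from .features import ExperimentDesign

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "score_annotations",
    "compute_metrics",
    "round_half_away",
    "detection_frequency",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def universe(self) -> int:
        """Number of evaluable features (every one is either TP or FN)."""
        return self.tp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """TPR, precision and F1; None marks an undefined (0/0) metric."""

    tpr: Optional[float]
    precision: Optional[float]
    f1: Optional[float]


def score_annotations(
    predicted: Dict[str, Optional[str]], truth: Dict[str, str]
) -> ConfusionCounts:
    """Count TP/FP/FN for predicted structures against spiked truth.

    ``predicted`` maps feature id -> asserted structure id (None or a
    missing key = unannotated). Every predicted feature must be in
    ``truth``; the evaluation universe must be closed.
    """
    unknown = set(predicted) - set(truth)
    if unknown:
        raise ValueError(f"predicted features outside the truth universe: {sorted(unknown)}")
    tp = fp = fn = 0
    for feature_id, true_structure in truth.items():
        asserted = predicted.get(feature_id)
        if asserted is None:
            fn += 1
        elif asserted == true_structure:
            tp += 1
        else:
            fn += 1  # not correctly annotated ...
            fp += 1  # ... and a wrong structure was asserted
    return ConfusionCounts(tp, fp, fn)


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """TPR = TP/(TP+FN), precision = TP/(TP+FP), F1 = their harmonic mean.

    A zero denominator leaves the metric undefined (None), never silently
    zero. Values are full precision; round for reporting with
    :func:`round_half_away`.
    """
    tpr = counts.tp / counts.universe if counts.universe > 0 else None
    denom = counts.tp + counts.fp
    precision = counts.tp / denom if denom > 0 else None
    f1 = None
    if tpr is not None and precision is not None and (tpr + precision) > 0:
        f1 = 2.0 * tpr * precision / (tpr + precision)
    elif tpr == 0 or precision == 0:
        f1 = 0.0 if tpr is not None and precision is not None else None
    return MetricSet(tpr, precision, f1)


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (so 0.8095 -> 0.81, -0.125 -> -0.13)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)


def detection_frequency(
    feature_samples: int, design_or_total: "ExperimentDesign | int"
) -> int:
    """Percent of samples in which a feature was detected, as a whole
    percent (half away from zero)."""
    if isinstance(design_or_total, ExperimentDesign):
        total = len(design_or_total.samples)
    else:
        total = int(design_or_total)
    if total <= 0:
        raise ValueError("design must contain at least one sample")
    if not 0 <= feature_samples <= total:
        raise ValueError(f"detected in {feature_samples} of {total} samples?")
    return int(round_half_away(100.0 * feature_samples / total, 0))
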