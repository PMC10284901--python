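"""Confusion-matrix metrics, moving-average post-processing and the
end-to-end seizure-detection evaluation.

For highly imbalanced detection tasks accuracy is dominated by the negative
class, so performance is summarized by sensitivity TP/(TP+FN), specificity
TN/(TN+FP) and their geometric mean (G-mean).  Because genuine seizure
episodes span several contiguous clips while classifier false positives tend
to be scattered, a centered moving average over the contiguous binary
prediction sequence followed by thresholding removes isolated positives while
preserving clustered runs; the reference operating point is a window of 9
clips with a threshold of 0.8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "PostprocessParams",
    "Metrics",
    "metrics",
    "confusion_from_sequences",
    "postprocess",
    "sweep_postprocess",
    "evaluate_pipeline",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PostprocessParams:
    window: int = 9
    threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.window <= 0 or self.window % 2 == 0:
            raise ValueError("window must be an odd positive integer")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")


@dataclass(frozen=True)
class Metrics:
    """Sensitivity, specificity, G-mean and accuracy; a metric whose
    denominator is zero is reported as None (undefined), never as 0."""

    sensitivity: float | None
    specificity: float | None
    g_mean: float | None
    accuracy: float


def metrics(counts: ConfusionCounts) -> Metrics:
    """Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    G-mean = sqrt(sensitivity * specificity), accuracy = (TP+TN)/total."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else None
    g = math.sqrt(sens * spec) if sens is not None and spec is not None else None
    acc = (counts.tp + counts.tn) / counts.total
    return Metrics(sensitivity=sens, specificity=spec, g_mean=g, accuracy=acc)


def confusion_from_sequences(labels, predictions) -> ConfusionCounts:
    """Binary confusion counts from equal-length 0/1 sequences."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if y.shape != p.shape:
        raise ValueError("label and prediction sequences must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))))


def postprocess(binary_sequence, params: PostprocessParams) -> np.ndarray:
    """Centered moving average of odd width (edges use the shrunken window
    that fits), then strict thresholding: output 1 where average > threshold."""
    x = np.asarray(binary_sequence, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty sequence")
    if not np.all((x == 0) | (x == 1)):
        raise ValueError("sequence values must be 0 or 1")
    h = params.window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, n - 1)
    avg = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return (avg > params.threshold).astype(int)


def sweep_postprocess(label_sequence, prediction_sequence, window_grid,
                      threshold_grid) -> pd.DataFrame:
    """Grid evaluation of post-processing parameters over a contiguous
    sequence; each row reports (window, threshold, accuracy, sensitivity,
    specificity).  ``df.attrs['best']`` maps each metric to its argmax row."""
    windows = list(window_grid)
    thresholds = list(threshold_grid)
    if not windows or not thresholds:
        raise ValueError("empty parameter grid")
    rows = []
    for w in windows:
        for th in thresholds:
            pp = postprocess(prediction_sequence, PostprocessParams(window=w, threshold=th))
            m = metrics(confusion_from_sequences(label_sequence, pp))
            rows.append({"window": w, "threshold": th, "accuracy": m.accuracy,
                         "sensitivity": m.sensitivity, "specificity": m.specificity})
    df = pd.DataFrame(rows)
    best = {}
    for col in ("accuracy", "sensitivity", "specificity"):
        vals = df[col].astype(float)
        if vals.notna().any():
            best[col] = df.loc[vals.idxmax()].to_dict()
    df.attrs["best"] = best
    return df


@dataclass
class ClassifiedSequence:
    """Contiguous per-clip evaluation report: raw predictions, post-processed
    decisions, and both confusion matrices with their metrics."""

    labels: np.ndarray
    raw_predictions: np.ndarray
    post_predictions: np.ndarray
    raw_counts: ConfusionCounts
    post_counts: ConfusionCounts
    raw_metrics: Metrics
    post_metrics: Metrics
    params: PostprocessParams


def evaluate_pipeline(model, X_contiguous, labels,
                      params: PostprocessParams | None = None,
                      positive_class: int = 1,
                      positive_threshold: float | None = None) -> ClassifiedSequence:
    """Classify a contiguous clip sequence, then post-process.

    ``model`` is any object with ``predict(X) -> labels`` (e.g. a trained
    :class:`~memspike.lsnn.LSNN`); both the raw and the post-processed
    confusion matrices are reported.  ``positive_threshold`` switches the
    per-clip decision from argmax to ``P(positive) >= threshold`` (a
    sensitivity-first operating point appropriate for detection screens;
    requires ``model.predict_proba``).
    """
    X = np.asarray(X_contiguous)
    y = np.asarray(labels).astype(int)
    if X.shape[0] == 0:
        raise ValueError("empty dataset")
    if X.shape[0] != y.shape[0]:
        raise ValueError("clips and labels must have equal length")
    if params is None:
        params = PostprocessParams()
    if positive_threshold is None:
        raw = (model.predict(X) == positive_class).astype(int)
    else:
        proba = model.predict_proba(X)[:, positive_class]
        raw = (proba >= positive_threshold).astype(int)
    y_bin = (y == positive_class).astype(int)
    post = postprocess(raw, params)
    raw_counts = confusion_from_sequences(y_bin, raw)
    post_counts = confusion_from_sequences(y_bin, post)
    return ClassifiedSequence(
        labels=y_bin, raw_predictions=raw, post_predictions=post,
        raw_counts=raw_counts, post_counts=post_counts,
        raw_metrics=metrics(raw_counts), post_metrics=metrics(post_counts),
        params=params)
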