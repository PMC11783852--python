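"""Confusion-matrix performance metrics and ROC analysis.

Five scalar metrics summarise a binary confusion matrix (class 2, the
isolated-microvessel class, is the positive class throughout the pipeline):

* precision  = TP / (TP + FP) — accuracy of positive predictions,
* recall     = TP / (TP + FN) — completeness of positive predictions,
* F-measure  = harmonic mean of precision and recall,
* fallout    = FP / (FP + TN) — the false-positive rate,
* threshold statistic = recall − fallout — the separation between the
  positive and negative score distributions; 1 for a perfect separator.

Degenerate denominators return 0 by convention (with a log note) rather
than raising, so metric curves remain defined at their endpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, UndefinedROCError

__all__ = [
    "ConfusionCounts",
    "PerformanceCurves",
    "precision",
    "recall",
    "fmeasure",
    "fallout",
    "threshold_stat",
    "confusion_from_labels",
    "roc_curve",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.fp, self.tn, self.fn)
        if any(c < 0 for c in counts):
            raise FormatError(f"confusion counts must be non-negative, got {counts}")
        if sum(counts) < 1:
            raise FormatError("confusion counts must total at least 1")


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.debug("%s undefined (zero denominator); returning 0 by convention", name)
        return 0.0
    return num / den


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn, "recall")


def fmeasure(c: ConfusionCounts) -> float:
    p, r = precision(c), recall(c)
    if p + r == 0:
        logger.debug("fmeasure undefined (precision + recall = 0); returning 0")
        return 0.0
    return 2 * p * r / (p + r)


def fallout(c: ConfusionCounts) -> float:
    return _ratio(c.fp, c.fp + c.tn, "fallout")


def threshold_stat(c: ConfusionCounts) -> float:
    """Recall minus false-positive rate; equals 1 for perfect separation."""
    return recall(c) - fallout(c)


def confusion_from_labels(
    y_true: np.ndarray, y_pred: np.ndarray, positive: int = 2
) -> ConfusionCounts:
    """One-vs-rest confusion counts for the given positive class."""
    t = np.asarray(y_true) == positive
    p = np.asarray(y_pred) == positive
    if t.shape != p.shape:
        raise FormatError("y_true and y_pred must have the same shape")
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC from per-pixel scores.

    Thresholds sweep the distinct score values in descending order (a
    prediction is positive when ``score >= threshold``); tied scores move
    along the curve together. The curve is anchored at (0, 0) and (1, 1).

    Parameters
    ----------
    scores : array of posterior scores for the positive class.
    labels : binary array (nonzero = positive).

    Returns
    -------
    (roc_points, auc) where roc_points is an (m, 2) array of (fpr, tpr)
    sorted by fpr.

    Raises
    ------
    UndefinedROCError
        If the labels contain a single class.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = (np.asarray(labels).ravel() != 0)
    if scores.shape != labels.shape:
        raise FormatError("scores and labels must have the same length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedROCError(
            f"ROC undefined: {n_pos} positive and {n_neg} negative labels"
        )
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    l = labels[order]
    # last index of each distinct-score run
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.append(distinct, s.size - 1)
    tps = np.cumsum(l)[idx]
    fps = (idx + 1) - tps
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return points, auc


@dataclass(frozen=True)
class PerformanceCurves:
    """Metric trajectories indexed by cumulative weak-learner count.

    ``epochs[i]`` is the number of trees in the partial ensemble whose
    held-out metrics fill row ``i`` of the five parallel metric lists.
    ``roc_points``/``auc`` describe the final (largest) ensemble's
    positive-class scores on the same evaluation pixels.
    """

    epochs: tuple[int, ...]
    precision: tuple[float, ...]
    recall: tuple[float, ...]
    fmeasure: tuple[float, ...]
    fallout: tuple[float, ...]
    threshold_stat: tuple[float, ...]
    roc_points: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        n = len(self.epochs)
        for name in ("precision", "recall", "fmeasure", "fallout", "threshold_stat"):
            if len(getattr(self, name)) != n:
                raise FormatError(f"curve {name} length differs from epochs")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epochs,
                "precision": self.precision,
                "recall": self.recall,
                "fmeasure": self.fmeasure,
                "fallout": self.fallout,
                "threshold_stat": self.threshold_stat,
            }
        )

    def roc_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.roc_points, columns=["fpr", "tpr"])

    def to_csv(self, curves_path: str | Path, roc_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(curves_path, index=False)
        if roc_path is not None:
            self.roc_frame().to_csv(roc_path, index=False)

    def plot(self, path: str | Path) -> None:
        """Six-panel figure: the five metrics versus epochs plus the ROC."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 3, figsize=(12, 7))
        series = [
            ("Precision", self.precision),
            ("Recall", self.recall),
            ("FMeasure", self.fmeasure),
            ("Fallout", self.fallout),
            ("Threshold", self.threshold_stat),
        ]
        for ax, (name, vals) in zip(axes.flat, series):
            ax.plot(self.epochs, vals, marker="o")
            ax.set_xlabel("epochs (trees)")
            ax.set_ylabel(name)
            ax.set_ylim(-0.05, 1.05)
        ax = axes.flat[5]
        ax.plot(self.roc_points[:, 0], self.roc_points[:, 1])
        ax.plot([0, 1], [0, 1], ls="--", c="gray")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"ROC (AUC = {self.auc:.3f})")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
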