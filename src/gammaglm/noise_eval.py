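"""Noisy-label flagging and evaluation metrics.

Detection treats "noisy" (mislabeled) as the positive class.  Two flagging
rules are provided: thresholding the credibility weights omega_i < Tv (the
default — small weight marks a suspect sample) and prediction/label
disagreement.  Metrics with a zero denominator are reported as ``None``
(undefined), never silently as zero; averaging code must skip undefined
cells and report how many contributed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = ["EvalReport", "flag_noisy", "detection_metrics", "accuracy_metrics"]

FLAG_MODES = ("weight", "disagreement")


@dataclass
class EvalReport:
    """The five headline metrics plus the noise-detection confusion counts.

    ``acc_noisy`` scores predictions against the observed (possibly
    contaminated) labels, ``acc_true`` against the ground-truth labels when
    available.  ``recall``/``precision``/``f1`` score the noise-detection
    flags against the true flip mask; undefined values are ``None``.
    """

    acc_noisy: float
    acc_true: Optional[float] = None
    recall: Optional[float] = None
    precision: Optional[float] = None
    f1: Optional[float] = None
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def as_dict(self) -> dict:
        return {
            "acc_noisy": self.acc_noisy, "acc_true": self.acc_true,
            "recall": self.recall, "precision": self.precision, "f1": self.f1,
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
        }


def flag_noisy(weights: Optional[ArrayLike] = None,
               Tv: Optional[float] = None,
               mode: str = "weight",
               predictions: Optional[ArrayLike] = None,
               y_observed: Optional[ArrayLike] = None) -> NDArray[np.bool_]:
    """Flag suspected mislabeled samples.

    ``weight`` mode flags omega_i < Tv; ``disagreement`` mode flags samples
    whose predicted label differs from the observed one.
    """
    if mode == "weight":
        if weights is None or Tv is None:
            raise ValueError("weight mode requires weights and Tv")
        return np.asarray(weights, dtype=float) < float(Tv)
    if mode == "disagreement":
        if predictions is None or y_observed is None:
            raise ValueError("disagreement mode requires predictions and y_observed")
        return np.asarray(predictions) != np.asarray(y_observed)
    raise ValueError(f"mode must be one of {FLAG_MODES}, got {mode!r}")


def detection_metrics(flags: ArrayLike, flip_mask: ArrayLike
                      ) -> tuple[Optional[float], Optional[float], Optional[float],
                                 tuple[int, int, int, int]]:
    """Recall, precision and F1 of noise detection, plus (tp, fp, fn, tn).

    recall = tp/(tp+fn), precision = tp/(tp+fp), f1 their harmonic mean;
    each is None when its denominator is zero.
    """
    flags = np.asarray(flags, dtype=bool)
    flip_mask = np.asarray(flip_mask, dtype=bool)
    if flags.shape != flip_mask.shape:
        raise ValueError("flags and flip_mask must have equal length")
    tp = int(np.sum(flags & flip_mask))
    fp = int(np.sum(flags & ~flip_mask))
    fn = int(np.sum(~flags & flip_mask))
    tn = int(np.sum(~flags & ~flip_mask))
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return recall, precision, f1, (tp, fp, fn, tn)


def accuracy_metrics(predictions: ArrayLike, y_observed: ArrayLike,
                     y_true: Optional[ArrayLike] = None
                     ) -> tuple[float, Optional[float]]:
    """(accuracy vs observed labels, accuracy vs true labels or None)."""
    predictions = np.asarray(predictions)
    y_observed = np.asarray(y_observed)
    if predictions.shape != y_observed.shape:
        raise ValueError("predictions and y_observed must have equal length")
    acc_noisy = float(np.mean(predictions == y_observed))
    acc_true: Optional[float] = None
    if y_true is not None:
        y_true = np.asarray(y_true)
        if y_true.shape != predictions.shape:
            raise ValueError("y_true length mismatch")
        acc_true = float(np.mean(predictions == y_true))
    return acc_noisy, acc_true


def evaluate(predictions: ArrayLike, dataset_flags: ArrayLike,
             y_observed: ArrayLike, y_true: Optional[ArrayLike] = None,
             flip_mask: Optional[ArrayLike] = None) -> EvalReport:
    """Assemble a full report from predictions and detection flags."""
    acc_noisy, acc_true = accuracy_metrics(predictions, y_observed, y_true)
    recall = precision = f1 = None
    tp = fp = fn = 0
    tn = len(np.asarray(y_observed))
    if flip_mask is not None:
        recall, precision, f1, (tp, fp, fn, tn) = detection_metrics(dataset_flags, flip_mask)
    return EvalReport(acc_noisy=acc_noisy, acc_true=acc_true, recall=recall,
                      precision=precision, f1=f1, tp=tp, fp=fp, fn=fn, tn=tn)
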