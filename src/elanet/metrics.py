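"""Segmentation evaluation: confusion-matrix accumulation, mean
intersection-over-union, pixel accuracy, and the binary cross-entropy
training loss.

With a single foreground class, mIoU averages the lesion IoU
``TP / (TP + FP + FN)`` and the background IoU (the same formula with the
class roles swapped, ``TN / (TN + FN + FP)``); classes absent from both
prediction and reference (zero union) are excluded from the mean, the
standard benchmark convention.  Both metrics are returned in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionMatrix", "accumulate", "miou", "acc", "bce_loss",
           "bce_with_logits"]


@dataclass
class ConfusionMatrix:
    """Pixel tallies for binary segmentation (k = 1 foreground class)."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def _check_binary(name: str, m: np.ndarray):
    vals = np.unique(m)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(
            f"{name} must be strictly binary (threshold first); found values {vals[:8]}"
        )


def accumulate(cm: ConfusionMatrix, pred: np.ndarray, gt: np.ndarray) -> ConfusionMatrix:
    """Add the per-pixel tallies of one mask pair; associative over images."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    _check_binary("pred", pred)
    _check_binary("gt", gt)
    p = pred.astype(bool)
    g = gt.astype(bool)
    return cm + ConfusionMatrix(
        tp=int(np.count_nonzero(p & g)),
        fp=int(np.count_nonzero(p & ~g)),
        fn=int(np.count_nonzero(~p & g)),
        tn=int(np.count_nonzero(~p & ~g)),
    )


def miou(cm: ConfusionMatrix) -> float:
    """Mean IoU over foreground and background, in percent."""
    if cm.total == 0:
        raise ValueError("mIoU is undefined on an empty confusion matrix")
    ious = []
    fg_union = cm.tp + cm.fp + cm.fn
    if fg_union > 0:
        ious.append(cm.tp / fg_union)
    bg_union = cm.tn + cm.fn + cm.fp
    if bg_union > 0:
        ious.append(cm.tn / bg_union)
    return 100.0 * float(np.mean(ious))


def acc(cm: ConfusionMatrix) -> float:
    """Pixel accuracy (TP + TN) / total, in percent."""
    if cm.total == 0:
        raise ValueError("accuracy is undefined on an empty confusion matrix")
    return 100.0 * (cm.tp + cm.tn) / cm.total


def bce_loss(prob: np.ndarray, gt: np.ndarray) -> float:
    """Mean binary cross-entropy of probabilities against a binary mask.

    Evaluated in logit space for numerical stability; probabilities are
    nudged away from exact 0/1 by one float32 step.
    """
    prob = np.asarray(prob, dtype=np.float64)
    gt = np.asarray(gt)
    if prob.shape != gt.shape:
        raise ValueError(f"shape mismatch: prob {prob.shape} vs gt {gt.shape}")
    eps = np.finfo(np.float32).tiny
    prob = np.clip(prob, eps, 1.0 - 2 ** -24)
    z = np.log(prob) - np.log1p(-prob)
    y = gt.astype(np.float64)
    # -[y log p + (1-y) log(1-p)] = max(z,0) - z*y + log(1 + exp(-|z|))
    return float(np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))))


def bce_with_logits(logits, target: np.ndarray):
    """Autodiff BCE on a logit Tensor (training path).

    Returns a scalar Tensor; gradient is (sigmoid(z) - y) / n.
    """
    from .nn.tensor import Tensor

    z = logits
    y = Tensor(np.asarray(target, dtype=np.float32))
    zd = z.data
    stable = np.maximum(zd, 0.0) - zd * y.data + np.log1p(np.exp(-np.abs(zd)))
    out = float(stable.mean())
    n = zd.size

    def backward(g):
        if z.requires_grad:
            s = 1.0 / (1.0 + np.exp(-zd))
            z._accum(g * (s - y.data) / n)

    return Tensor._node(np.float32(out), (z,), backward)
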