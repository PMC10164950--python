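"""Training objective (BCE + soft Dice) and pixel-level evaluation metrics.

The segmentation objective is the sum of binary cross-entropy and a soft
Dice complement, applied to the fused probability map and — under deep
supervision — to each of the six side maps as well.  Evaluation follows
the standard pixel confusion-count metrics: accuracy, sensitivity,
specificity and F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

BCE_EPS = 1e-7
DICE_SMOOTH = 1.0


# ---------------------------------------------------------------------------
# losses — numpy reference implementations
# ---------------------------------------------------------------------------


def _check_shapes(pred, target):
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    return pred, target


def bce_loss(pred, target, eps: float = BCE_EPS) -> float:
    """Mean binary cross-entropy; predictions clamped to [eps, 1-eps]."""
    pred, target = _check_shapes(pred, target)
    p = np.clip(pred, eps, 1.0 - eps)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))


def dice_loss(pred, target, smooth: float = DICE_SMOOTH) -> float:
    """Soft Dice complement: 1 - (2*sum(p*t)+s) / (sum(p)+sum(t)+s)."""
    pred, target = _check_shapes(pred, target)
    if smooth < 0:
        raise ValueError("smooth must be >= 0")
    inter = float((pred * target).sum())
    denom = float(pred.sum() + target.sum())
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)


@dataclass
class LossBreakdown:
    bce: float
    dice: float

    @property
    def total(self) -> float:
        return self.bce + self.dice


def combined_loss(fused, sides, target, deep_supervision: bool = True,
                  smooth: float = DICE_SMOOTH) -> tuple[float, LossBreakdown]:
    """Total BCE+Dice over the fused map and (optionally) all side maps.

    Returns (total, fused-map breakdown); the fused map's own breakdown is
    reported separately so training logs stay interpretable.
    """
    fb = LossBreakdown(bce_loss(fused, target), dice_loss(fused, target, smooth))
    total = fb.total
    if deep_supervision:
        for s in sides:
            total += bce_loss(s, target) + dice_loss(s, target, smooth)
    return total, fb


# ---------------------------------------------------------------------------
# losses — differentiable tensor versions (used by the training loop)
# ---------------------------------------------------------------------------


def bce_loss_t(pred: Tensor, target: np.ndarray, eps: float = BCE_EPS) -> Tensor:
    if pred.data.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.data.shape} vs target {target.shape}")
    t = target.astype(pred.data.dtype)
    p = nn.clamp(pred, eps, 1.0 - eps)
    return -nn.tmean(Tensor(t) * nn.log(p) + Tensor(1.0 - t) * nn.log(1.0 - p))


def dice_loss_t(pred: Tensor, target: np.ndarray, smooth: float = DICE_SMOOTH) -> Tensor:
    if pred.data.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.data.shape} vs target {target.shape}")
    t = Tensor(target.astype(pred.data.dtype))
    inter = nn.tsum(pred * t)
    denom = float(target.sum()) + smooth
    # denominator contains sum(pred), a tensor: build 1 - (2i+s)/(sum_p + denom_t)
    sum_p = nn.tsum(pred)
    # (2*inter + smooth) / (sum_p + denom) via log-free ops: use reciprocal
    num = inter * 2.0 + smooth
    return 1.0 - _tdiv(num, sum_p + denom)


def _tdiv(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise a/b for scalar tensors."""
    out = a.data / b.data

    def bwd(g):
        nn._accumulate(a, g / b.data)
        nn._accumulate(b, -g * a.data / (b.data ** 2))

    return nn._node(np.asarray(out), (a, b), bwd)


def combined_loss_t(fused: Tensor, sides: list[Tensor], target: np.ndarray,
                    deep_supervision: bool = True,
                    smooth: float = DICE_SMOOTH) -> tuple[Tensor, LossBreakdown]:
    fb_bce = bce_loss_t(fused, target)
    fb_dice = dice_loss_t(fused, target, smooth)
    breakdown = LossBreakdown(float(fb_bce.data), float(fb_dice.data))
    total = fb_bce + fb_dice
    if deep_supervision:
        for s in sides:
            total = total + bce_loss_t(s, target) + dice_loss_t(s, target, smooth)
    return total, breakdown


# ---------------------------------------------------------------------------
# confusion counts and metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP, self.TN + other.TN, self.FN + other.FN
        )


def _check_binary(a, name):
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return a.astype(bool)


def confusion_counts(pred_mask, true_mask) -> ConfusionCounts:
    pred = _check_binary(pred_mask, "pred_mask")
    true = _check_binary(true_mask, "true_mask")
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    return ConfusionCounts(
        TP=int((pred & true).sum()),
        FP=int((pred & ~true).sum()),
        TN=int((~pred & ~true).sum()),
        FN=int((~pred & true).sum()),
    )


@dataclass
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float

    def as_dict(self) -> dict:
        return {
            "Acc": self.accuracy,
            "Se": self.sensitivity,
            "Sp": self.specificity,
            "F1": self.f1,
        }


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def metrics(c: ConfusionCounts) -> Metrics:
    """Acc, Se, Sp, F1 from pixel confusion counts.

    Degenerate denominators yield NaN with a warning rather than a
    silent 0 or 1.
    """
    if c.total == 0:
        raise ValueError("metrics require at least one evaluated pixel")
    return Metrics(
        accuracy=(c.TP + c.TN) / c.total,
        sensitivity=_safe_div(c.TP, c.TP + c.FN, "sensitivity"),
        specificity=_safe_div(c.TN, c.TN + c.FP, "specificity"),
        f1=_safe_div(2 * c.TP, 2 * c.TP + c.FP + c.FN, "F1"),
    )


def dataset_metrics(pairs, average: str = "micro") -> Metrics:
    """Metrics over (pred_mask, true_mask) pairs.

    ``micro`` pools confusion counts over all images (the default);
    ``macro`` averages per-image metric values.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no mask pairs supplied")
    if average == "micro":
        total = ConfusionCounts()
        for pred, true in pairs:
            total = total + confusion_counts(pred, true)
        return metrics(total)
    if average == "macro":
        per = [metrics(confusion_counts(p, t)) for p, t in pairs]
        return Metrics(
            accuracy=float(np.nanmean([m.accuracy for m in per])),
            sensitivity=float(np.nanmean([m.sensitivity for m in per])),
            specificity=float(np.nanmean([m.specificity for m in per])),
            f1=float(np.nanmean([m.f1 for m in per])),
        )
    raise ValueError(f"unknown averaging mode {average!r}")
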