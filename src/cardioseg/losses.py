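"""Training losses: soft Dice, pixel-wise cross-entropy, and their weighted sum.

The compound loss is  L = alpha * L_ce + beta * L_dice  with defaults
alpha = 1, beta = 0.2.  Cross-entropy treats every pixel as an independent
4-way classification against a one-hot target and is averaged over pixels,
so the alpha:beta balance does not depend on image resolution.  The Dice
loss is 1 minus a soft overlap ratio computed over the three foreground
classes (RV, myocardium, LV) jointly by default — Dice is there precisely
to keep the small foreground structures from being drowned out by the
background-dominated cross-entropy; a per-class-averaged variant is
available.

Each loss also returns its analytic gradient with respect to the predicted
probabilities, so the chain through the softmax is explicit and cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LossWeights", "dice_loss", "cross_entropy_loss", "combined_loss",
           "one_hot", "softmax_backward"]

N_CLASSES = 4
_FG = slice(1, None)  # foreground classes: RV, myo, LV


@dataclass
class LossWeights:
    """Weights and stabilizers of the compound loss.

    alpha scales the pixel-wise cross-entropy, beta the Dice loss; dice_eps
    keeps the Dice denominator positive on empty masks; ce_floor clamps
    probabilities inside the logarithm.
    """

    alpha: float = 1.0
    beta: float = 0.2
    dice_eps: float = 1e-10
    ce_floor: float = 1e-12
    dice_mode: str = "joint"  # "joint" over foreground, or "per_class"

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.alpha == 0 and self.beta == 0:
            raise ValueError("alpha and beta cannot both be zero")
        if self.dice_eps <= 0:
            raise ValueError("dice_eps must be positive")
        if not 0 < self.ce_floor < 1e-3:
            raise ValueError("ce_floor must lie in (0, 1e-3)")
        if self.dice_mode not in ("joint", "per_class"):
            raise ValueError(f"unknown dice_mode {self.dice_mode!r}")


def one_hot(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """(N,H,W) integer labels -> (N,C,H,W) float32 one-hot target."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(f"labels outside [0, {n_classes})")
    eye = np.eye(n_classes, dtype=np.float32)
    return np.ascontiguousarray(eye[labels].transpose(0, 3, 1, 2))


def _check_pair(pred: np.ndarray, target: np.ndarray):
    # losses and their gradients are accumulated in float64 so closed-form
    # values hold to ~1e-9 even on float32 network outputs
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"pred shape {pred.shape} != target shape {target.shape}")
    if pred.ndim != 4:
        raise ValueError("expected (N,C,H,W) probability and target arrays")
    return pred, target


def _check_one_hot(target: np.ndarray):
    sums = target.sum(axis=1)
    if not (np.all((target == 0) | (target == 1)) and np.allclose(sums, 1.0)):
        raise ValueError("target is not one-hot: each pixel needs exactly one 1")


def dice_loss(pred: np.ndarray, target: np.ndarray, dice_eps: float = 1e-10,
              mode: str = "joint", return_grad: bool = False):
    """Soft Dice loss 1 - 2|A.B| / (|A| + |B| + eps) over foreground classes.

    |A.B| is the pixel-wise product of predicted probability and one-hot
    target summed over the foreground; |A| and |B| are the respective sums.
    In "per_class" mode the three foreground classes are scored separately
    and averaged.  Differentiable in ``pred``.
    """
    pred, target = _check_pair(pred, target)
    p, y = pred[:, _FG], target[:, _FG]
    if mode == "joint":
        inter = float((p * y).sum())
        denom = float(y.sum() + p.sum()) + dice_eps
        loss = 1.0 - 2.0 * inter / denom
        if not return_grad:
            return loss
        grad = np.zeros_like(pred)
        grad[:, _FG] = -2.0 * y / denom + 2.0 * inter / denom ** 2
        return loss, grad
    elif mode == "per_class":
        n_fg = p.shape[1]
        losses = np.empty(n_fg)
        grad = np.zeros_like(pred) if return_grad else None
        for c in range(n_fg):
            pc, yc = p[:, c], y[:, c]
            inter = float((pc * yc).sum())
            denom = float(yc.sum() + pc.sum()) + dice_eps
            losses[c] = 1.0 - 2.0 * inter / denom
            if return_grad:
                grad[:, 1 + c] = (-2.0 * yc / denom + 2.0 * inter / denom ** 2) / n_fg
        loss = float(losses.mean())
        return (loss, grad) if return_grad else loss
    raise ValueError(f"unknown dice mode {mode!r}")


def cross_entropy_loss(pred: np.ndarray, target: np.ndarray,
                       ce_floor: float = 1e-12, return_grad: bool = False):
    """Pixel-wise multi-class cross-entropy -sum_j y_j log P_j, pixel-averaged.

    Probabilities are clamped below at ``ce_floor`` inside the log.
    """
    pred, target = _check_pair(pred, target)
    _check_one_hot(target)
    n_pix = pred.shape[0] * pred.shape[2] * pred.shape[3]
    clamped = np.maximum(pred, ce_floor)
    loss = float(-(target * np.log(clamped)).sum() / n_pix)
    if not return_grad:
        return loss
    grad = np.where(pred > ce_floor, -target / clamped, 0.0) / n_pix
    return loss, grad


def combined_loss(pred: np.ndarray, target: np.ndarray,
                  weights: LossWeights | None = None, return_grad: bool = False):
    """alpha * cross_entropy + beta * dice (defaults alpha=1, beta=0.2)."""
    w = weights or LossWeights()
    if return_grad:
        ce, gce = cross_entropy_loss(pred, target, w.ce_floor, return_grad=True)
        dl, gdl = dice_loss(pred, target, w.dice_eps, w.dice_mode, return_grad=True)
        return w.alpha * ce + w.beta * dl, w.alpha * gce + w.beta * gdl
    ce = cross_entropy_loss(pred, target, w.ce_floor)
    dl = dice_loss(pred, target, w.dice_eps, w.dice_mode)
    return w.alpha * ce + w.beta * dl


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """Chain a gradient w.r.t. softmax outputs back to the logits.

    Result dtype follows the inputs' promotion.
    """
    probs = np.asarray(probs)
    inner = (dprobs * probs).sum(axis=1, keepdims=True)
    return probs * (dprobs - inner)
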