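"""Segmentation losses: cross-entropy, soft Dice, and their Combo mixture.

The Combo loss is

    L = alpha * CE_beta - (1 - alpha) * DiceTerm

where ``CE_beta`` is the class-probability cross-entropy with the positive
term weighted ``beta`` and the negative term ``1 - beta`` (``beta = 0.5``
recovers half the plain BCE), and ``DiceTerm`` is the smoothed soft Dice
coefficient averaged over classes (the per-class sum rescaled by the class
count so the two terms share an O(1) scale).  ``alpha = 1`` reduces L to the
weighted cross-entropy; ``alpha = 0`` to the negative smoothed Dice term.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, make_op, tmean, tsum

_EPS = 1e-6


def _as_target(t) -> np.ndarray:
    return np.asarray(t, dtype=np.float32)


def _safe_log(p: Tensor, eps: float = _EPS) -> Tensor:
    """log of p clamped to [eps, 1-eps] with a straight-through gradient.

    A hard clamp would zero the gradient once a sigmoid output saturates,
    permanently silencing rare classes; passing 1/clamped(p) through instead
    keeps the composed sigmoid-BCE gradient equal to (p - t) in the
    saturated regime, as in logit-space cross-entropy."""
    pc = np.clip(p.data, eps, 1.0 - eps)
    return make_op(np.log(pc), [(p, lambda g: g / pc)])


def weighted_bce(p: Tensor, t, beta: float = 0.5) -> Tensor:
    """Mean of -(beta * t * log p + (1 - beta) * (1 - t) * log(1 - p))."""
    t = _as_target(t)
    pos = _safe_log(p) * t
    neg = _safe_log(1.0 - p) * (1.0 - t)
    return -(tmean(pos) * beta + tmean(neg) * (1.0 - beta))


def bce(p: Tensor, t) -> Tensor:
    """Plain (unweighted) binary cross-entropy over all voxels and classes."""
    t = _as_target(t)
    return -tmean(_safe_log(p) * t + _safe_log(1.0 - p) * (1.0 - t))


def dice_term(p: Tensor, t, smooth: float = 1.0) -> Tensor:
    """Smoothed soft Dice coefficient, averaged over the class axis (axis 1)."""
    t = _as_target(t)
    axes = (0,) + tuple(range(2, p.ndim))
    inter = tsum(p * t, axis=axes)
    denom = tsum(p, axis=axes) + t.sum(axis=axes)
    return tmean((inter * 2.0 + smooth) / (denom + smooth))


def dice_loss(p: Tensor, t, smooth: float = 1.0) -> Tensor:
    return 1.0 - dice_term(p, t, smooth)


def combo_loss(p: Tensor, t, alpha: float = 0.5, beta: float = 0.5,
               smooth: float = 1.0) -> Tensor:
    if not (0.0 <= alpha <= 1.0 and 0.0 <= beta <= 1.0):
        raise ValueError("alpha and beta must lie in [0, 1]")
    ce = weighted_bce(p, t, beta)
    dt = dice_term(p, t, smooth)
    return ce * alpha - dt * (1.0 - alpha)


def get_loss(name: str, alpha: float = 0.5, beta: float = 0.5):
    """Return ``loss(p, t) -> Tensor`` for one of bce / dice / bce_dice / combo."""
    if name == "bce":
        return bce
    if name == "dice":
        return dice_loss
    if name == "bce_dice":
        return lambda p, t: bce(p, t) + dice_loss(p, t)
    if name == "combo":
        return lambda p, t: combo_loss(p, t, alpha=alpha, beta=beta)
    raise ValueError(f"unknown loss {name!r}")
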