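"""Compound focal + soft-Dice segmentation loss (values and gradients).

Both losses act on the sigmoid probability map p and the binary target y:

* focal: mean over voxels of ``-alpha_t (1 - p_t)^gamma log(p_t)`` with
  ``p_t = p`` on foreground / ``1-p`` on background and ``alpha_t = alpha``
  / ``1-alpha`` respectively; at gamma = 0, alpha = 0.5 it reduces to half
  the binary cross-entropy.
* soft Dice: ``1 - (2 sum(p y) + s) / (sum(p) + sum(y) + s)`` summed over
  the whole batch, with smooth constant s.

The gradients returned are with respect to p; the network's sigmoid layer
chains them to logits.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-7


def focal_loss(prob, target, gamma: float = 2.0, alpha: float = 0.25,
               with_grad: bool = False):
    p = np.asarray(prob, dtype=np.float64)
    y = np.asarray(target, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError("probability map and target shapes differ")
    if gamma < 0 or not (0.0 < alpha < 1.0):
        raise ValueError("need gamma >= 0 and alpha in (0, 1)")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    pt = np.where(y > 0.5, p, 1.0 - p)
    at = np.where(y > 0.5, alpha, 1.0 - alpha)
    one_m = 1.0 - pt
    loss = float(np.mean(-at * one_m**gamma * np.log(pt)))
    if not with_grad:
        return loss
    # d/dpt of -at (1-pt)^g log pt, then chain dpt/dp = +/- 1
    if gamma == 0:
        dpt = -at / pt
    else:
        dpt = at * (gamma * one_m ** (gamma - 1) * np.log(pt) - one_m**gamma / pt)
    grad = np.where(y > 0.5, dpt, -dpt) / p.size
    return loss, grad


def soft_dice_loss(prob, target, smooth: float = 1.0, with_grad: bool = False):
    p = np.asarray(prob, dtype=np.float64)
    y = np.asarray(target, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError("probability map and target shapes differ")
    num = 2.0 * float((p * y).sum()) + smooth
    den = float(p.sum() + y.sum()) + smooth
    loss = 1.0 - num / den
    if not with_grad:
        return loss
    grad = -(2.0 * y * den - num) / den**2
    return loss, grad


def combined_loss(prob, target, gamma=2.0, alpha=0.25, smooth=1.0,
                  w_focal=1.0, w_dice=1.0, with_grad: bool = False):
    """Weighted focal + soft-Dice; weights must not both vanish."""
    if w_focal < 0 or w_dice < 0 or (w_focal == 0 and w_dice == 0):
        raise ValueError("loss weights must be non-negative, not both zero")
    if with_grad:
        lf, gf = focal_loss(prob, target, gamma, alpha, with_grad=True)
        ld, gd = soft_dice_loss(prob, target, smooth, with_grad=True)
        return (w_focal * lf + w_dice * ld,
                w_focal * gf + w_dice * gd,
                {"focal": lf, "dice": ld})
    lf = focal_loss(prob, target, gamma, alpha)
    ld = soft_dice_loss(prob, target, smooth)
    return w_focal * lf + w_dice * ld
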