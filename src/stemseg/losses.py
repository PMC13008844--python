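"""Training objectives for binary stem segmentation.

The composite objective is a convex combination of Dice loss and pixel-wise
binary cross-entropy,

    L_CD = alpha * L_Dice + (1 - alpha) * L_CE,

chosen because the slender main stem occupies only a small fraction of the
image: cross-entropy alone is dominated by the background class, while the
Dice term directly optimizes region overlap and is insensitive to foreground
sparsity.  All functions accept either plain numpy arrays or autodiff
:class:`~stemseg.nn.Tensor` inputs, so the same formulas serve the training
graph and standalone evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.tensor import Tensor

__all__ = ["LossConfig", "ce_loss", "dice_loss", "composite_loss"]


@dataclass(frozen=True)
class LossConfig:
    """Weighting and numerical-safety constants of the composite loss.

    alpha : Dice weight in [0, 1]; 0.5 by default, giving equal pull to the
        region-overlap and pixel-classification terms.
    eps : Dice smoothing term; rescues the 0/0 case of an empty mask.
    clip : probabilities are clamped to [clip, 1-clip] before the logarithm.
    """

    alpha: float = 0.5
    eps: float = 1e-6
    clip: float = 1e-7

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _check_shapes(p, g):
    ps = p.shape if hasattr(p, "shape") else np.shape(p)
    gs = g.shape if hasattr(g, "shape") else np.shape(g)
    if ps != gs:
        raise ValueError(f"probability/label shape mismatch: {ps} vs {gs}")


def ce_loss(p, g, clip: float = 1e-7):
    """Mean binary cross-entropy −(1/N) Σ [g ln p + (1−g) ln(1−p)].

    ``p`` is the predicted foreground probability per pixel, ``g`` the binary
    ground-truth label.  Probabilities are clamped to [clip, 1−clip].
    """
    _check_shapes(p, g)
    if _is_tensor(p):
        pc = p.clip(clip, 1.0 - clip)
        terms = g * pc.log() + (1.0 - g) * (1.0 - pc).log()
        return -terms.mean()
    pc = np.clip(np.asarray(p, dtype=float), clip, 1.0 - clip)
    g = np.asarray(g, dtype=float)
    return float(-np.mean(g * np.log(pc) + (1.0 - g) * np.log(1.0 - pc)))


def dice_loss(p, g, eps: float = 1e-6):
    """Soft Dice loss 1 − (2 Σ p·g + eps) / (Σ p + Σ g + eps), in [0, 1]."""
    _check_shapes(p, g)
    if _is_tensor(p) or _is_tensor(g):
        inter = (p * g).sum() if _is_tensor(p) else (g * p).sum()
        gsum = g.sum() if _is_tensor(g) else float(np.sum(g))
        psum = p.sum() if _is_tensor(p) else float(np.sum(p))
        return 1.0 - (2.0 * inter + eps) / (psum + gsum + eps)
    p = np.asarray(p, dtype=float)
    g = np.asarray(g, dtype=float)
    return float(1.0 - (2.0 * np.sum(p * g) + eps) / (np.sum(p) + np.sum(g) + eps))


def composite_loss(p, g, config: LossConfig = LossConfig()):
    """alpha-weighted Dice + (1−alpha) cross-entropy."""
    a = config.alpha
    d = dice_loss(p, g, config.eps)
    c = ce_loss(p, g, config.clip)
    return a * d + (1.0 - a) * c
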