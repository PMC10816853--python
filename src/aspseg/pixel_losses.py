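"""Pixel-level segmentation losses: BCE, soft dice, focal, and their hybrid.

Pixel-level losses compare prediction and ground truth pixel by pixel,
treating pixels as independent entities.  All functions accept either
plain ``numpy`` arrays (returning a ``float``) or autodiff
:class:`~aspseg.autodiff.Tensor` predictions (returning a ``Tensor`` so
gradients flow to the prediction).

BCE and focal losses are averaged over pixels, so magnitudes are
comparable across image resolutions; the dice loss is a single global
quotient over the whole mask.  Two dice dialects are provided: the
default keeps the plain intersection in the numerator, the "standard"
dialect uses the conventional 2× intersection (so that, for hard masks
and vanishing smoothing, ``1 - dice_loss`` equals the dice similarity
coefficient).
"""

from __future__ import annotations

from dataclasses import dataclass

from .autodiff import Tensor, as_tensor
from .exceptions import ConfigError
from .masks import check_same_shape, validate_bin_mask, validate_prob_mask

__all__ = ["PixelLossConfig", "bce_loss", "dice_loss", "focal_loss", "hybrid_pixel_loss"]

DEFAULT_CLAMP = 1e-7


@dataclass
class PixelLossConfig:
    """Hyperparameters of the hybrid pixel-level loss α·dice + β·BCE."""

    alpha: float = 1.0          # dice weight
    beta: float = 1.0           # BCE weight
    dice_epsilon: float = 1.0   # smoothing term in the dice quotient
    prob_clamp: float = DEFAULT_CLAMP
    dice_dialect: str = "paper"  # "paper" (plain numerator) or "standard" (2x)

    def validate(self) -> "PixelLossConfig":
        if self.alpha < 0 or self.beta < 0:
            raise ConfigError("alpha and beta must be non-negative")
        if self.dice_epsilon <= 0:
            raise ConfigError("dice_epsilon must be positive")
        if not (0.0 < self.prob_clamp < 0.5):
            raise ConfigError("prob_clamp must lie in (0, 0.5)")
        if self.dice_dialect not in ("paper", "standard"):
            raise ConfigError(f"unknown dice dialect {self.dice_dialect!r}")
        return self


def _prepare(pred, gt):
    """Validate a (pred, gt) pair; return (Tensor pred, Tensor gt, was_array)."""
    check_same_shape(pred, gt)
    validate_prob_mask(pred)
    gt_arr = validate_bin_mask(gt)
    was_array = not isinstance(pred, Tensor)
    return as_tensor(pred), as_tensor(gt_arr), was_array


def _finish(loss: Tensor, was_array: bool):
    return loss.item() if was_array else loss


def bce_loss(pred, gt, clamp: float = DEFAULT_CLAMP):
    """Binary cross-entropy, mean over pixels.

    −[y log ŷ + (1−y) log(1−ŷ)] with ŷ clamped into [clamp, 1−clamp]
    before the logarithm for numerical stability.
    """
    if not (0.0 < clamp < 0.5):
        raise ConfigError("clamp must lie in (0, 0.5)")
    p, y, was_array = _prepare(pred, gt)
    pc = p.clip(clamp, 1.0 - clamp)
    loss = -(y * pc.log() + (1.0 - y) * (1.0 - pc).log()).mean()
    return _finish(loss, was_array)


def dice_loss(pred, gt, epsilon: float = 1.0, dialect: str = "paper"):
    """Soft dice loss, a single global quotient over the mask.

    dialect="paper":    1 − (Σ ŷy + ϵ) / (Σ ŷ + Σ y + ϵ)
    dialect="standard": 1 − (2Σ ŷy + ϵ) / (Σ ŷ + Σ y + ϵ)
    """
    if epsilon <= 0:
        raise ConfigError("epsilon must be positive")
    if dialect not in ("paper", "standard"):
        raise ConfigError(f"unknown dice dialect {dialect!r}")
    p, y, was_array = _prepare(pred, gt)
    inter = (p * y).sum()
    num = inter * (2.0 if dialect == "standard" else 1.0) + epsilon
    den = p.sum() + y.sum() + epsilon
    return _finish(1.0 - num / den, was_array)


def focal_loss(pred, gt, upsilon: float, clamp: float = DEFAULT_CLAMP):
    """Focal loss, mean over pixels of −(1−Ŷ_t)^υ log(Ŷ_t).

    Ŷ_t is the estimated probability of the true class (ŷ where y=1,
    1−ŷ where y=0).  υ=0 recovers BCE; larger υ down-weights
    easy-to-classify pixels.
    """
    if upsilon < 0:
        raise ConfigError("upsilon (focusing parameter) must be non-negative")
    p, y, was_array = _prepare(pred, gt)
    pc = p.clip(clamp, 1.0 - clamp)
    yt = y * pc + (1.0 - y) * (1.0 - pc)       # probability of the true class
    loss = -((1.0 - yt) ** upsilon * yt.log()).mean()
    return _finish(loss, was_array)


def hybrid_pixel_loss(pred, gt, cfg: PixelLossConfig | None = None):
    """Static hybrid pixel loss α·dice + β·BCE."""
    cfg = (cfg or PixelLossConfig()).validate()
    d = dice_loss(pred, gt, cfg.dice_epsilon, cfg.dice_dialect)
    b = bce_loss(pred, gt, cfg.prob_clamp)
    return cfg.alpha * d + cfg.beta * b
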