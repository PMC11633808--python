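"""Focal log losses for the adversarial pair and the weighted generator total.

Both networks are trained with the focal log loss

    FL(p) = -(1 - p)^gamma * log(p + eps)

where ``p`` is the predicted probability in the *target* class (the label
probability y is always unity), ``gamma`` down-weights easy voxels and
``eps`` sits inside the logarithm so the loss stays finite at p = 0.

The total generator loss combines the supervised segmentation term with the
adversarial term derived from the discriminator's loss on the generated
sample:

    L_gen = alpha * FL_G + beta * (1 - FL_D)

with default weights alpha = 20 and beta = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossParams",
    "focal_log_loss",
    "generator_total_loss",
    "focal_loss_from_probs",
    "focal_softmax_grad",
]


@dataclass
class LossParams:
    """Focal-loss and generator-weighting hyperparameters.

    gamma : focusing exponent (>= 0); 0 recovers the plain log loss.
    eps   : small positive offset inside the log, preventing infinite loss.
    alpha : weight of the supervised generator term.
    beta  : weight of the adversarial generator term.
    """

    gamma: float = 2.0
    eps: float = 1e-7
    alpha: float = 20.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not (0 < self.eps < 1e-2):
            raise ValueError("eps must be a small positive offset")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")


def focal_log_loss(p_target: np.ndarray, params: LossParams | None = None):
    """Per-voxel focal log loss and its mean.

    Parameters
    ----------
    p_target : array-like
        Predicted probability in the target class at each voxel, in [0, 1].

    Returns
    -------
    (loss_grid, mean_loss)
        Per-voxel losses (same shape as input) and their mean.
    """
    params = params or LossParams()
    p = np.asarray(p_target, dtype=np.float64)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p_target must lie in [0, 1]")
    loss = -((1.0 - p) ** params.gamma) * np.log(p + params.eps)
    return loss, float(loss.mean()) if loss.size else 0.0


def generator_total_loss(fl_g: float, fl_d_on_generated: float,
                         params: LossParams | None = None) -> float:
    """Weighted total generator loss ``alpha * FL_G + beta * (1 - FL_D)``.

    ``fl_d_on_generated`` is the discriminator's focal loss evaluated on the
    generated sample; minimizing the total therefore *maximizes* FL_D, the
    usual min-max adversarial coupling.
    """
    params = params or LossParams()
    if not (np.isfinite(fl_g) and np.isfinite(fl_d_on_generated)):
        raise ValueError("loss terms must be finite")
    return float(params.alpha * fl_g + params.beta * (1.0 - fl_d_on_generated))


# ---------------------------------------------------------------------------
# softmax-coupled forms used by the training loop
# ---------------------------------------------------------------------------

def focal_loss_from_probs(probs: np.ndarray, target: np.ndarray,
                          params: LossParams) -> float:
    """Mean focal loss of softmax ``probs`` (..., C) against integer
    ``target`` (...) class indices (channel-last)."""
    p_t = np.take_along_axis(probs, target[..., None], axis=-1)[..., 0]
    _, mean = focal_log_loss(np.clip(p_t, 0.0, 1.0), params)
    return mean


def focal_softmax_grad(probs: np.ndarray, target: np.ndarray,
                       params: LossParams) -> np.ndarray:
    """Gradient of the mean focal loss w.r.t. the softmax *logits*.

    ``probs`` (..., C) are the softmax outputs (channel-last), ``target``
    (...) the integer class indices. Chains dL/dp through the softmax
    Jacobian: dp_t/dz_j = p_t (1[j = t] - p_j).
    """
    g, eps = params.gamma, params.eps
    p_t = np.take_along_axis(probs, target[..., None], axis=-1)[..., 0]
    p_t = np.clip(p_t, 0.0, 1.0 - 1e-12)
    if g == 0:
        dldp = -1.0 / (p_t + eps)
    else:
        dldp = g * (1.0 - p_t) ** (g - 1.0) * np.log(p_t + eps) \
            - (1.0 - p_t) ** g / (p_t + eps)
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, target[..., None], 1.0, axis=-1)
    dz = (dldp * p_t)[..., None] * (onehot - probs)
    # mean reduction over all voxels (not classes)
    return (dz / target.size).astype(probs.dtype)
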