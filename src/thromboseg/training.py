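"""Focal loss and the shared training-loop configuration.

Focal loss for binary segmentation, mean-reduced over pixels:

    FL(p_t) = -alpha_t * (1 - p_t)^gamma * log(p_t)

with p_t = p on foreground pixels and 1-p on background, and
alpha_t = alpha on foreground, 1-alpha on background.  gamma=0 and
alpha=0.5 reduce it to 0.5x binary cross-entropy.  Probabilities are
clamped to [1e-7, 1-1e-7] before the log.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, astensor

__all__ = ["focal_loss", "TrainConfig", "FOCAL_EPS"]

FOCAL_EPS = 1e-7


def focal_loss(probs, gt, alpha: float = 0.25, gamma: float = 2.0):
    """Mean focal loss of predicted probabilities against a binary mask.

    ``probs`` may be a :class:`Tensor` (returns a scalar Tensor on the
    autograd graph) or a plain array (returns a float).  Shapes must match.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    is_tensor = isinstance(probs, Tensor)
    p = astensor(probs)
    y = np.asarray(gt, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs gt {y.shape}")
    p = p.clip(FOCAL_EPS, 1.0 - FOCAL_EPS)
    pt = p * y + (1.0 - p) * (1.0 - y)
    at = alpha * y + (1.0 - alpha) * (1.0 - y)
    loss = -(Tensor(at) * (1.0 - pt) ** gamma * pt.log()).mean()
    return loss if is_tensor else loss.item()


@dataclass(frozen=True)
class TrainConfig:
    """SGD settings shared by backbone and head training loops.

    The defaults mirror the study protocol: plain SGD, learning rate
    0.0001 for the attention backbone and 0.005 for the Bi-CLSTM head
    (the head loop substitutes its own default when ``lr`` is None).
    """

    lr: float | None = None
    momentum: float = 0.9
    steps: int = 200
    seed: int = 0
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0

    def __post_init__(self):
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if self.lr is not None and self.lr < 0:
            raise ValueError("lr must be >= 0")
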