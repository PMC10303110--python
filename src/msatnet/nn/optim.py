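"""Optimisers and weight constraints."""

from __future__ import annotations

import numpy as np

from .autograd import Parameter

__all__ = ["Adam", "max_norm_rescale"]


class Adam:
    """Adam with bias-corrected moment estimates.

    Only parameters with ``trainable=True`` are updated, which is how
    backbone freezing during adapter fine-tuning is enforced.
    """

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params: list[Parameter] = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if not getattr(p, "trainable", True) or p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype, copy=False)
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def max_norm_rescale(weight: np.ndarray, c: float, axis: int = 0) -> np.ndarray:
    """Project each weight vector onto the L2 ball of radius ``c``.

    ``axis`` indexes the elements within one constrained vector; for a
    dense weight of shape [in, out] with axis=0, each output unit's
    incoming vector is constrained independently:
    w <- w * min(1, c / ||w||_2).
    """
    if c <= 0:
        raise ValueError(f"max-norm bound must be positive, got {c}")
    norms = np.sqrt((weight * weight).sum(axis=axis, keepdims=True))
    scale = np.minimum(1.0, c / np.maximum(norms, 1e-12))
    return weight * scale
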