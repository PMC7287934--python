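"""Adam optimizer with optional warmup-then-inverse-sqrt-decay schedule."""

from __future__ import annotations

from typing import Dict

import numpy as np

from .autograd import Tensor

__all__ = ["Adam"]


class Adam:
    """Adam over a named parameter dict, with global-norm gradient clipping.

    ``schedule="constant"`` uses ``lr`` throughout; ``schedule="warmup"``
    ramps linearly to ``lr`` over ``warmup_steps`` then decays as
    ``sqrt(warmup_steps / step)`` (the standard Transformer recipe, with the
    peak rate made explicit).
    """

    def __init__(
        self,
        params: Dict[str, Tensor],
        lr: float = 1e-3,
        betas=(0.9, 0.98),
        eps: float = 1e-9,
        grad_clip: float = 1.0,
        schedule: str = "constant",
        warmup_steps: int = 200,
    ):
        if schedule not in ("constant", "warmup"):
            raise ValueError(f"unknown schedule: {schedule!r}")
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.grad_clip = grad_clip
        self.schedule = schedule
        self.warmup_steps = max(1, warmup_steps)
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def _rate(self) -> float:
        if self.schedule == "constant":
            return self.lr
        t = self.t
        if t <= self.warmup_steps:
            return self.lr * t / self.warmup_steps
        return self.lr * (self.warmup_steps / t) ** 0.5

    def step(self) -> float:
        """Apply one update from accumulated gradients; returns the rate used."""
        self.t += 1
        lr_t = self._rate()
        if self.grad_clip > 0:
            total = 0.0
            for p in self.params.values():
                if p.grad is not None:
                    total += float((p.grad.astype(np.float64) ** 2).sum())
            norm = total ** 0.5
            scale = self.grad_clip / norm if norm > self.grad_clip else 1.0
        else:
            scale = 1.0
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / bc1
            v_hat = self.v[k] / bc2
            p.data -= (lr_t * m_hat / (np.sqrt(v_hat) + self.eps)).astype(np.float32)
        return lr_t

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
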