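"""AdamW with per-parameter-group learning-rate scaling and a cosine schedule."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class AdamW:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, lr_scales=None):
        """`params`: list of Tensors. `lr_scales`: optional per-tensor multiplier
        (used for layer-wise learning-rate decay)."""
        self.params: list[Tensor] = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.lr_scales = list(lr_scales) if lr_scales is not None else [1.0] * len(self.params)
        self.m = [np.zeros_like(p.data, dtype=float) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=float) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v, s in zip(self.params, self.m, self.v, self.lr_scales):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            lr = self.lr * s
            upd = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data = p.data - lr * (upd + self.weight_decay * p.data)


def cosine_warmup_lr(step: int, total_steps: int, base_lr: float, warmup_steps: int) -> float:
    """Linear warmup to `base_lr` over `warmup_steps`, then cosine decay to 0."""
    if warmup_steps > 0 and step < warmup_steps:
        return base_lr * (step + 1) / warmup_steps
    if total_steps <= warmup_steps:
        return base_lr
    frac = (step - warmup_steps) / (total_steps - warmup_steps)
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * min(max(frac, 0.0), 1.0)))
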