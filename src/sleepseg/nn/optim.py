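"""Adam optimizer with the classic per-update learning-rate decay
``lr_t = lr / (1 + decay * t)`` (the convention of the era's frameworks for
a "decay rate"; ``decay=0`` gives plain Adam)."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 learning_rate: float = 1e-4, decay: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        self.params = params
        self.grads = grads
        self.lr = learning_rate
        self.decay = decay
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]

    def step(self) -> None:
        """One in-place update using the gradients currently stored in the
        layers' gradient buffers."""
        self.t += 1
        lr_t = self.lr / (1.0 + self.decay * self.t)
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g.astype(np.float64) ** 2 - v)
            update = lr_t * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
            p -= update.astype(p.dtype)
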