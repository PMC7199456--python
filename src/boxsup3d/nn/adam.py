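"""ADAM optimizer over a flat list of parameter arrays."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in self.params]

    def step(self, grads, lr_scale: float = 1.0) -> None:
        """One update; ``lr_scale`` multiplies the step size (eta, or gamma*eta)."""
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = np.asarray(g, dtype=np.float64)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p -= (self.lr * lr_scale * update).astype(p.dtype)
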