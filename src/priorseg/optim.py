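"""RMSProp with Nesterov momentum.

RMSProp rescales each gradient coordinate by a running root-mean-square of
past gradients (decay 0.9, epsilon 1e-6); Nesterov momentum (0.9) is then
composed with the rescaled step: with delta = -lr * g / sqrt(accu + eps),

    v   <- mu * v + delta
    p   <- p + mu * v + delta

which is the standard 'apply momentum to the update' formulation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RMSPropNesterov"]


class RMSPropNesterov:
    def __init__(
        self,
        params: dict[str, np.ndarray],
        learning_rate: float = 2.5e-4,
        rho: float = 0.9,
        momentum: float = 0.9,
        eps: float = 1e-6,
    ):
        self.params = params
        self.lr = learning_rate
        self.rho = rho
        self.momentum = momentum
        self.eps = eps
        self.accu = {k: np.zeros_like(v) for k, v in params.items()}
        self.vel = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            g = grads[k]
            a = self.accu[k]
            a *= self.rho
            a += (1 - self.rho) * g * g
            delta = -self.lr * g / np.sqrt(a + self.eps)
            v = self.vel[k]
            v *= self.momentum
            v += delta
            p += self.momentum * v + delta
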