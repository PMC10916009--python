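"""Adam optimiser and exponential learning-rate decay."""

from __future__ import annotations

import numpy as np

from .layers import Param


class ExponentialDecay:
    """lr(epoch) = lr_init * rate**epoch."""

    def __init__(self, lr_init: float, rate: float = 0.96):
        if lr_init <= 0 or not 0 < rate <= 1:
            raise ValueError("lr_init must be > 0 and rate in (0, 1]")
        self.lr_init = lr_init
        self.rate = rate

    def __call__(self, epoch: int) -> float:
        return self.lr_init * self.rate**epoch


class Adam:
    """Adaptive-moment stochastic gradient descent."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
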