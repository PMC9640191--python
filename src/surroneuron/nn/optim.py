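"""First-order optimizers with global-norm gradient clipping.

``nadam`` is Adam accelerated with Nesterov momentum; ``adamax`` is the
infinity-norm Adam variant.
"""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, lr: float, clipnorm: float = 1.0):
        self.lr = lr
        self.clipnorm = clipnorm
        self.t = 0
        self.state: dict = {}
        self.last_grad_norm: float = 0.0

    def _clip(self, grads):
        total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
        self.last_grad_norm = total
        if self.clipnorm and total > self.clipnorm:
            scale = self.clipnorm / (total + 1e-12)
            return {k: g * scale for k, g in grads.items()}, min(total, self.clipnorm)
        return grads, total

    def step(self, params: dict, grads: dict) -> None:
        """In-place update; ``params`` and ``grads`` map names to arrays."""
        grads, applied = self._clip(grads)
        self.last_applied_norm = applied
        self.t += 1
        for k, g in grads.items():
            self._update(k, params[k], g)

    def _update(self, key, p, g):
        raise NotImplementedError


class Adam(Optimizer):
    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7, clipnorm=1.0):
        super().__init__(lr, clipnorm)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def _update(self, key, p, g):
        m, v = self.state.setdefault(key, (np.zeros_like(p), np.zeros_like(p)))
        m[:] = self.beta1 * m + (1 - self.beta1) * g
        v[:] = self.beta2 * v + (1 - self.beta2) * g * g
        mhat = m / (1 - self.beta1**self.t)
        vhat = v / (1 - self.beta2**self.t)
        p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Nadam(Adam):
    def _update(self, key, p, g):
        m, v = self.state.setdefault(key, (np.zeros_like(p), np.zeros_like(p)))
        m[:] = self.beta1 * m + (1 - self.beta1) * g
        v[:] = self.beta2 * v + (1 - self.beta2) * g * g
        mhat = m / (1 - self.beta1 ** (self.t + 1))
        vhat = v / (1 - self.beta2**self.t)
        m_nesterov = self.beta1 * mhat + (1 - self.beta1) * g / (1 - self.beta1**self.t)
        p -= self.lr * m_nesterov / (np.sqrt(vhat) + self.eps)


class Adamax(Optimizer):
    def __init__(self, lr=2e-3, beta1=0.9, beta2=0.999, eps=1e-7, clipnorm=1.0):
        super().__init__(lr, clipnorm)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def _update(self, key, p, g):
        m, u = self.state.setdefault(key, (np.zeros_like(p), np.zeros_like(p)))
        m[:] = self.beta1 * m + (1 - self.beta1) * g
        u[:] = np.maximum(self.beta2 * u, np.abs(g))
        p -= self.lr / (1 - self.beta1**self.t) * m / (u + self.eps)


def make_optimizer(name: str, lr: float | None = None, clipnorm: float = 1.0) -> Optimizer:
    name = name.lower()
    if name == "adam":
        return Adam(lr=lr or 1e-3, clipnorm=clipnorm)
    if name in ("adam_nesterov", "nadam"):
        return Nadam(lr=lr or 1e-3, clipnorm=clipnorm)
    if name == "adamax":
        return Adamax(lr=lr or 2e-3, clipnorm=clipnorm)
    raise ValueError(f"unknown optimizer: {name}")
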