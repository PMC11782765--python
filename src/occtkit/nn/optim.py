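"""First-order optimizers (Keras-style update rules)."""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, params, lr: float):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is not None:
                self._update(i, p)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def _update(self, i, p):
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params, lr=0.01, momentum=0.0):
        super().__init__(params, lr)
        self.momentum = momentum
        self.v = [np.zeros_like(p.data) for p in self.params]

    def _update(self, i, p):
        self.v[i] = self.momentum * self.v[i] - self.lr * p.grad
        p.data += self.v[i]


class Adam(Optimizer):
    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def _update(self, i, p):
        b1, b2 = self.beta1, self.beta2
        self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
        self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
        mhat = self.m[i] / (1 - b1 ** self.t)
        vhat = self.v[i] / (1 - b2 ** self.t)
        p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Adamax(Optimizer):
    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.u = [np.zeros_like(p.data) for p in self.params]

    def _update(self, i, p):
        b1 = self.beta1
        self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
        self.u[i] = np.maximum(self.beta2 * self.u[i], np.abs(p.grad))
        p.data -= (self.lr / (1 - b1 ** self.t)) * self.m[i] / (self.u[i] + self.eps)


class Nadam(Adam):
    def _update(self, i, p):
        b1, b2 = self.beta1, self.beta2
        self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
        self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
        mhat = self.m[i] / (1 - b1 ** (self.t + 1))
        vhat = self.v[i] / (1 - b2 ** self.t)
        m_nesterov = b1 * mhat + (1 - b1) * p.grad / (1 - b1 ** self.t)
        p.data -= self.lr * m_nesterov / (np.sqrt(vhat) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, params, lr=0.001, rho=0.9, eps=1e-7):
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self.v = [np.zeros_like(p.data) for p in self.params]

    def _update(self, i, p):
        self.v[i] = self.rho * self.v[i] + (1 - self.rho) * p.grad ** 2
        p.data -= self.lr * p.grad / (np.sqrt(self.v[i]) + self.eps)


OPTIMIZERS = {
    "sgd": SGD,
    "adam": Adam,
    "adamax": Adamax,
    "nadam": Nadam,
    "rmsprop": RMSprop,
}


def make_optimizer(name: str, params, lr: float) -> Optimizer:
    key = name.lower()
    if key not in OPTIMIZERS:
        raise ValueError(f"unknown optimizer {name!r}; choose from "
                         f"{sorted(OPTIMIZERS)}")
    return OPTIMIZERS[key](params, lr=lr)
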