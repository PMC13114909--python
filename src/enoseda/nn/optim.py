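"""Optimizers and the cosine learning-rate schedule used by all stages."""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor


class Optimizer:
    def __init__(self, params: list[Tensor], lr: float):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):  # pragma: no cover - abstract
        raise NotImplementedError


class SGD(Optimizer):
    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad


class Adam(Optimizer):
    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        super().__init__(params, lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)


class CosineAnnealing:
    """Decays each optimizer's lr from its base value to 0 at the final epoch."""

    def __init__(self, optimizers: list[Optimizer], total_epochs: int):
        if total_epochs < 1:
            raise ValueError("total_epochs must be >= 1")
        self.optimizers = list(optimizers)
        self.base = [opt.lr for opt in self.optimizers]
        self.total = total_epochs

    def set_epoch(self, epoch: int):
        if self.total == 1:
            frac = 0.0
        else:
            frac = epoch / (self.total - 1)
        scale = 0.5 * (1.0 + math.cos(math.pi * min(frac, 1.0)))
        for opt, b in zip(self.optimizers, self.base):
            opt.lr = b * scale
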