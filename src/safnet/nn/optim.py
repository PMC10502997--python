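"""Optimization: Adam with decoupled-from-nothing L2 weight decay, and a
reduce-on-plateau learning-rate scheduler."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class Adam:
    """Adam optimizer; ``weight_decay`` adds an L2 term to the gradient."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.betas = betas
        self.eps = float(eps)
        self.weight_decay = float(weight_decay)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class ReduceLROnPlateau:
    """Halve (by ``factor``) the learning rate when a monitored metric stops
    improving.

    The rate is reduced as soon as ``patience`` consecutive checks have shown
    no improvement over the best value seen, i.e. a metric flat for
    ``patience`` checks triggers the reduction on the next (patience-th
    stagnant) check.
    """

    def __init__(self, optimizer: Adam, mode: str = "max", factor: float = 0.5,
                 patience: int = 10, min_lr: float = 0.0):
        if not (0.0 < factor < 1.0):
            raise ValueError("factor must be in (0, 1)")
        if patience < 1:
            raise ValueError("patience must be >= 1")
        if mode not in ("max", "min"):
            raise ValueError("mode must be 'max' or 'min'")
        self.optimizer = optimizer
        self.mode = mode
        self.factor = float(factor)
        self.patience = int(patience)
        self.min_lr = float(min_lr)
        self.best: float | None = None
        self.num_bad = 0

    def _improved(self, metric: float) -> bool:
        if self.best is None:
            return True
        return metric > self.best if self.mode == "max" else metric < self.best

    def step(self, metric: float) -> None:
        if self._improved(metric):
            self.best = float(metric)
            self.num_bad = 0
            return
        self.num_bad += 1
        if self.num_bad >= self.patience:
            self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
            self.num_bad = 0
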