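"""Decoupled-weight-decay Adam and a per-step one-cycle learning-rate schedule."""

from __future__ import annotations

import numpy as np


class AdamW:
    """Adam with decoupled weight decay.

    Weight decay is applied directly to the parameters, scaled by the current
    learning rate, independent of the adaptive gradient step.  Batch-norm
    scale/shift parameters can be exempted by passing them in ``no_decay``.
    """

    def __init__(
        self,
        params,
        lr: float = 1.58e-4,
        betas: tuple = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 5e-4,
        no_decay=(),
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._no_decay = set(id(p) for p in no_decay)
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self._t += 1
        bc1 = 1.0 - self.beta1**self._t
        bc2 = 1.0 - self.beta2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            mhat = m / bc1
            vhat = v / bc2
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and id(p) not in self._no_decay:
                p.value -= lr * self.weight_decay * p.value


class OneCycleLR:
    """Cosine one-cycle schedule stepped once per optimizer step.

    Ramps from ``max_lr / div_factor`` up to ``max_lr`` over the first
    ``pct_start`` fraction of ``total_steps``, then anneals down to
    ``max_lr / (div_factor * final_div_factor)``.
    """

    def __init__(
        self,
        max_lr: float,
        total_steps: int,
        pct_start: float = 0.3,
        div_factor: float = 25.0,
        final_div_factor: float = 1e4,
    ):
        if total_steps < 1:
            raise ValueError("total_steps must be >= 1")
        if not 0.0 < pct_start < 1.0:
            raise ValueError("pct_start must lie in (0, 1)")
        self.max_lr = max_lr
        self.total_steps = total_steps
        self.pct_start = pct_start
        self.initial_lr = max_lr / div_factor
        self.min_lr = self.initial_lr / final_div_factor
        self._step = 0

    @staticmethod
    def _cos_anneal(start: float, end: float, frac: float) -> float:
        return end + (start - end) * (1 + np.cos(np.pi * frac)) / 2.0

    def lr_at(self, step: int) -> float:
        up_steps = max(1, int(round(self.pct_start * self.total_steps)))
        if step <= up_steps:
            return self._cos_anneal(self.initial_lr, self.max_lr, step / up_steps)
        down = (step - up_steps) / max(1, self.total_steps - up_steps)
        return self._cos_anneal(self.max_lr, self.min_lr, min(down, 1.0))

    def step(self) -> float:
        """Advance one step and return the learning rate to use."""
        self._step += 1
        return self.lr_at(self._step)
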