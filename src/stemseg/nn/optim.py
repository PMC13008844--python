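"""Adam optimizer (Kingma & Ba) over :class:`Parameter` lists."""

from __future__ import annotations

import numpy as np

from .tensor import Parameter

__all__ = ["Adam"]


class Adam:
    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> int:
        """Apply one update; frozen (requires_grad=False) or grad-less
        parameters are skipped.  Returns the number of tensors updated."""
        self._t += 1
        updated = 0
        for i, p in enumerate(self.params):
            if not p.requires_grad or p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * (g * g)
            mhat = self._m[i] / (1 - self.b1**self._t)
            vhat = self._v[i] / (1 - self.b2**self._t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            updated += 1
        return updated
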