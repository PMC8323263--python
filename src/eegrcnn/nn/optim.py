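"""Stochastic gradient descent with classical momentum.

After every step, parameters carrying an absolute-value bound (the indRNN
recurrent weights) are clipped back into ``[-clip_abs, clip_abs]``.
"""

from __future__ import annotations

import numpy as np

from .layers import Param


class SGD:
    def __init__(self, params: list[Param], lr: float = 0.01, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v
            if p.clip_abs is not None:
                np.clip(p.data, -p.clip_abs, p.clip_abs, out=p.data)
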