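"""Stochastic gradient descent with momentum and L2 weight decay."""

from __future__ import annotations

import numpy as np

from . import _kernels


class SGD:
    def __init__(self, params, lr, momentum=0.9, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if _kernels.HAVE_NUMBA and p.data.dtype == np.float32 \
                    and g.dtype == np.float32:
                _kernels.sgd_update(p.data.ravel(), v.ravel(),
                                    np.ascontiguousarray(g).ravel(),
                                    self.lr, self.momentum, self.weight_decay)
                continue
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
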