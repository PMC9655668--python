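"""Type-generic array helpers.

The attention operators are specified as pure math on feature maps; the same
formulas also run inside the trainable network.  These helpers dispatch on
input type so one implementation serves both plain numpy arrays (pure,
oracle-checkable) and autograd tensors (trainable).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from . import autograd
from .autograd import Tensor


def sigmoid(x):
    """Numerically stable logistic function (no overflow at large |x|)."""
    if isinstance(x, Tensor):
        return x.sigmoid()
    return expit(np.asarray(x))


def relu(x):
    if isinstance(x, Tensor):
        return x.relu()
    return np.maximum(np.asarray(x), 0)


def mean(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.mean(axis=axis, keepdims=keepdims)
    return np.mean(x, axis=axis, keepdims=keepdims)


def amax(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.max(axis=axis, keepdims=keepdims)
    return np.max(x, axis=axis, keepdims=keepdims)


def concatenate(xs, axis=0):
    if any(isinstance(x, Tensor) for x in xs):
        return autograd.concatenate(xs, axis=axis)
    return np.concatenate(xs, axis=axis)


def reshape(x, shape):
    if isinstance(x, Tensor):
        return x.reshape(shape)
    return np.reshape(x, shape)


def matmul(a, b):
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        a = a if isinstance(a, Tensor) else Tensor(a)
        return a @ b
    return a @ b


def asarray(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x)
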