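"""Layer/module abstractions over the autograd tensors.

The design mirrors the familiar module/parameter pattern: a :class:`Module`
owns named parameters (autograd tensors with ``requires_grad=True``) and
submodules, exposes recursive iteration for optimizers and parameter audits,
and supports flat ``state_dict`` export for single-file checkpoints.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .autograd import Tensor
from .conv import conv2d

DTYPE = np.float32


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def add_module(self, name, module):
        self._modules[name] = module
        object.__setattr__(self, name, module)

    # -- traversal ------------------------------------------------------------
    def named_parameters(self, prefix=""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix=""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def param_count(self) -> int:
        """Number of trainable scalars (batch-norm running stats excluded)."""
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization --------------------------------------------------------
    def state_dict(self):
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({"buffer:" + k: v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        for k, v in state.items():
            if k.startswith("buffer:"):
                name = k[len("buffer:"):]
                for bname, buf in self.named_buffers():
                    if bname == name:
                        buf[...] = v
                        break
                else:
                    raise KeyError(f"unknown buffer {name!r}")
            else:
                if k not in params:
                    raise KeyError(f"unknown parameter {k!r}")
                params[k].data[...] = v

    def save(self, path):
        np.savez(path, **self.state_dict())

    def load(self, path):
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, dilation=1, groups=1, bias=True, rng=None):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.dilation, self.groups = dilation, groups
        rng = rng or np.random.default_rng(0)
        fan_out = out_channels * kernel_size * kernel_size // groups
        std = float(np.sqrt(2.0 / fan_out))
        w = rng.normal(0.0, std, (out_channels, in_channels // groups,
                                  kernel_size, kernel_size)).astype(DTYPE)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=DTYPE), requires_grad=True) \
            if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding,
                      self.dilation, self.groups)


class BatchNorm2d(Module):
    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Tensor(np.ones(num_features, dtype=DTYPE), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features, dtype=DTYPE), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(num_features, dtype=DTYPE))
        self.register_buffer("running_var", np.ones(num_features, dtype=DTYPE))

    def forward(self, x):
        x = _as_tensor(x)
        xd = x.data
        gamma, beta = self.weight, self.bias
        training = self.training
        use_kernel = _kernels.HAVE_NUMBA and xd.dtype == np.float32 and training
        if use_kernel:
            xd = np.ascontiguousarray(xd)
            c = xd.shape[1]
            mu = np.empty(c, dtype=np.float32)
            inv = np.empty(c, dtype=np.float32)
            xhat = np.empty_like(xd)
            out = np.empty_like(xd)
            _kernels.bn_forward(xd, gamma.data, beta.data, self.eps, mu, inv, xhat, out)
            var = 1.0 / inv ** 2 - self.eps
        else:
            if training:
                mu = xd.mean(axis=(0, 2, 3))
                var = xd.var(axis=(0, 2, 3))
            else:
                mu, var = self.running_mean, self.running_var
            inv = (1.0 / np.sqrt(var + self.eps)).astype(xd.dtype)
            xhat = (xd - mu.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
            out = xhat * gamma.data.reshape(1, -1, 1, 1) + beta.data.reshape(1, -1, 1, 1)
        if training:
            self.running_mean *= 1.0 - self.momentum
            self.running_mean += self.momentum * mu
            self.running_var *= 1.0 - self.momentum
            self.running_var += self.momentum * var

        def backward(g):
            if use_kernel:
                g = np.ascontiguousarray(g)
                gx = np.empty_like(g)
                ggamma = np.empty_like(gamma.data)
                gbeta = np.empty_like(beta.data)
                _kernels.bn_backward(g, xhat, gamma.data, inv, True, gx, ggamma, gbeta)
                return gx, ggamma, gbeta
            gbeta = g.sum(axis=(0, 2, 3))
            ggamma = (g * xhat).sum(axis=(0, 2, 3))
            gscale = (gamma.data * inv).reshape(1, -1, 1, 1)
            if training:
                m = g.shape[0] * g.shape[2] * g.shape[3]
                gx = gscale * (g - gbeta.reshape(1, -1, 1, 1) / m
                               - xhat * ggamma.reshape(1, -1, 1, 1) / m)
            else:
                gx = gscale * g
            return (gx.astype(xd.dtype, copy=False),
                    ggamma.astype(xd.dtype, copy=False),
                    gbeta.astype(xd.dtype, copy=False))

        return Tensor._make(out, (x, gamma, beta), backward)


class ReLU(Module):
    def forward(self, x):
        return _as_tensor(x).relu()


class SiLU(Module):
    def forward(self, x):
        return _as_tensor(x).silu()


class Sigmoid(Module):
    def forward(self, x):
        return _as_tensor(x).sigmoid()


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self.add_module(str(i), layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i):
        return self.layers[i]
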