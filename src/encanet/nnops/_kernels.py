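"""Compiled inner loops for the depthwise convolution hot path.

Depthwise convolutions are memory-bound; the jitted kernels fuse the
per-tap multiply-accumulate into one pass over the data.  If numba is
unavailable the callers fall back to vectorized numpy.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=True)
def sgd_update(p, v, g, lr, momentum, weight_decay):
    for i in range(p.size):
        vi = momentum * v[i] + g[i] + weight_decay * p[i]
        v[i] = vi
        p[i] -= lr * vi


@njit(cache=True, fastmath=True)
def sq_norm(g):
    acc = 0.0
    for i in range(g.size):
        acc += g[i] * g[i]
    return acc


@njit(cache=True, fastmath=True)
def silu_forward(x, out, sig):
    for i in range(x.size):
        s = 1.0 / (1.0 + np.exp(-x.flat[i]))
        sig.flat[i] = s
        out.flat[i] = x.flat[i] * s


@njit(cache=True, fastmath=True)
def silu_backward(g, x, sig, gx):
    for i in range(g.size):
        s = sig.flat[i]
        gx.flat[i] = g.flat[i] * (s + x.flat[i] * s * (1.0 - s))


@njit(cache=True, fastmath=True)
def bn_forward(x, gamma, beta, eps, mu, inv, xhat, out):
    n, c, h, w = x.shape
    m = n * h * w
    for ci in range(c):
        acc = 0.0
        acc2 = 0.0
        for ni in range(n):
            for i in range(h):
                for j in range(w):
                    v = x[ni, ci, i, j]
                    acc += v
                    acc2 += v * v
        mean = acc / m
        var = acc2 / m - mean * mean
        if var < 0.0:
            var = 0.0
        mu[ci] = mean
        iv = 1.0 / np.sqrt(var + eps)
        inv[ci] = iv
        ga, be = gamma[ci], beta[ci]
        for ni in range(n):
            for i in range(h):
                for j in range(w):
                    xh = (x[ni, ci, i, j] - mean) * iv
                    xhat[ni, ci, i, j] = xh
                    out[ni, ci, i, j] = ga * xh + be


@njit(cache=True, fastmath=True)
def bn_backward(g, xhat, gamma, inv, training, gx, ggamma, gbeta):
    n, c, h, w = g.shape
    m = n * h * w
    for ci in range(c):
        sg = 0.0
        sgx = 0.0
        for ni in range(n):
            for i in range(h):
                for j in range(w):
                    gv = g[ni, ci, i, j]
                    sg += gv
                    sgx += gv * xhat[ni, ci, i, j]
        gbeta[ci] = sg
        ggamma[ci] = sgx
        scale = gamma[ci] * inv[ci]
        if training:
            mg, mgx = sg / m, sgx / m
            for ni in range(n):
                for i in range(h):
                    for j in range(w):
                        gx[ni, ci, i, j] = scale * (g[ni, ci, i, j] - mg
                                                    - xhat[ni, ci, i, j] * mgx)
        else:
            for ni in range(n):
                for i in range(h):
                    for j in range(w):
                        gx[ni, ci, i, j] = scale * g[ni, ci, i, j]


@njit(cache=True, fastmath=True)
def dw_forward(xp, w, out, stride, dilation):
    n, c, _, _ = xp.shape
    ho, wo = out.shape[2], out.shape[3]
    kh, kw = w.shape[1], w.shape[2]
    if stride == 1:
        # tap loops outside, unit-stride column loop inside (vectorizable)
        for ni in range(n):
            for ci in range(c):
                for oi in range(ho):
                    row = out[ni, ci, oi]
                    for oj in range(wo):
                        row[oj] = 0.0
                    for i in range(kh):
                        src = xp[ni, ci, oi + i * dilation]
                        for j in range(kw):
                            wij = w[ci, i, j]
                            off = j * dilation
                            for oj in range(wo):
                                row[oj] += wij * src[oj + off]
        return
    for ni in range(n):
        for ci in range(c):
            for oi in range(ho):
                base_i = oi * stride
                for oj in range(wo):
                    base_j = oj * stride
                    acc = np.float32(0.0)
                    for i in range(kh):
                        ii = base_i + i * dilation
                        for j in range(kw):
                            acc += w[ci, i, j] * xp[ni, ci, ii, base_j + j * dilation]
                    out[ni, ci, oi, oj] = acc


@njit(cache=True, fastmath=True)
def dw_backward(xp, w, g, gxp, gw, stride, dilation):
    n, c, _, _ = xp.shape
    ho, wo = g.shape[2], g.shape[3]
    kh, kw = w.shape[1], w.shape[2]
    if stride == 1:
        for ni in range(n):
            for ci in range(c):
                for oi in range(ho):
                    grow = g[ni, ci, oi]
                    for i in range(kh):
                        src = xp[ni, ci, oi + i * dilation]
                        dst = gxp[ni, ci, oi + i * dilation]
                        for j in range(kw):
                            wij = w[ci, i, j]
                            off = j * dilation
                            acc = np.float32(0.0)
                            for oj in range(wo):
                                acc += grow[oj] * src[oj + off]
                            gw[ci, i, j] += acc
                            for oj in range(wo):
                                dst[oj + off] += grow[oj] * wij
        return
    for ni in range(n):
        for ci in range(c):
            for oi in range(ho):
                base_i = oi * stride
                for oj in range(wo):
                    base_j = oj * stride
                    gv = g[ni, ci, oi, oj]
                    for i in range(kh):
                        ii = base_i + i * dilation
                        for j in range(kw):
                            jj = base_j + j * dilation
                            gxp[ni, ci, ii, jj] += gv * w[ci, i, j]
                            gw[ci, i, j] += gv * xp[ni, ci, ii, jj]
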