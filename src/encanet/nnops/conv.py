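"""2-D convolution (with stride, padding, dilation, groups) on numpy arrays.

Three code paths keep the common cases fast on a single CPU core:

* pointwise (1x1, stride 1) convolutions run as batched BLAS matmuls;
* depthwise convolutions run through compiled per-tap loops (numba), with a
  vectorized shift-and-accumulate fallback;
* everything else goes through im2col + BLAS.

``conv2d`` accepts either plain numpy arrays (forward only) or autograd
:class:`~encanet.nnops.autograd.Tensor` inputs, in which case a backward
closure is attached.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import _kernels
from .autograd import Tensor


def _contig(a):
    return a if a.flags["C_CONTIGUOUS"] else np.ascontiguousarray(a)


def _pad(x, padding):
    if padding == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))


def _windows(xp, kh, kw, stride, dilation):
    keh = (kh - 1) * dilation + 1
    kew = (kw - 1) * dilation + 1
    v = sliding_window_view(xp, (keh, kew), axis=(2, 3))
    return v[:, :, ::stride, ::stride, ::dilation, ::dilation]


def conv2d_output_shape(h, w, k, stride=1, padding=0, dilation=1):
    ke = (k - 1) * dilation + 1
    return (h + 2 * padding - ke) // stride + 1, (w + 2 * padding - ke) // stride + 1


def _scatter_windows(gwin, in_shape, kh, kw, stride, padding, dilation):
    """Accumulate per-window gradients (N,C,kh,kw,Ho,Wo) back onto the input."""
    n, c, h, w = in_shape
    hp, wp = h + 2 * padding, w + 2 * padding
    ho, wo = gwin.shape[-2:]
    gxp = np.zeros((n, c, hp, wp), dtype=gwin.dtype)
    for i in range(kh):
        for j in range(kw):
            gxp[:, :, i * dilation: i * dilation + ho * stride: stride,
                j * dilation: j * dilation + wo * stride: stride] += gwin[:, :, i, j]
    if padding:
        gxp = gxp[:, :, padding:-padding, padding:-padding]
    return gxp


def conv2d(x, weight, bias=None, stride=1, padding=0, dilation=1, groups=1):
    """Cross-correlation of `x` (N,C,H,W) with `weight` (O, C/groups, kh, kw)."""
    is_tensor = isinstance(x, Tensor) or isinstance(weight, Tensor)
    xd = x.data if isinstance(x, Tensor) else np.asarray(x)
    wd = weight.data if isinstance(weight, Tensor) else np.asarray(weight)
    bd = None
    if bias is not None:
        bd = bias.data if isinstance(bias, Tensor) else np.asarray(bias)

    n, cin, h, w = xd.shape
    cout, cpg, kh, kw = wd.shape
    if cin != cpg * groups:
        raise ValueError(f"channel mismatch: input has {cin}, weight expects {cpg * groups}")

    pointwise = kh == 1 and kw == 1 and stride == 1 and padding == 0 and groups == 1
    depthwise = groups == cin and cpg == 1 and cout == cin

    if pointwise:
        xr = xd.reshape(n, cin, h * w)
        out = np.matmul(wd.reshape(cout, cin), xr).reshape(n, cout, h, w)
        cache = ("pw", xr)
        ho, wo = h, w
    elif depthwise:
        xp = _pad(xd, padding)
        ho, _ = conv2d_output_shape(h, h, kh, stride, padding, dilation)
        _, wo = conv2d_output_shape(w, w, kw, stride, padding, dilation)
        out = np.empty((n, cin, ho, wo), dtype=xd.dtype)
        if _kernels.HAVE_NUMBA and xd.dtype == np.float32:
            _kernels.dw_forward(_contig(xp), _contig(wd[:, 0]), out,
                                stride, dilation)
        else:
            # shift-and-accumulate: one fused multiply-add per kernel tap
            out[...] = 0
            for i in range(kh):
                for j in range(kw):
                    out += wd[:, 0, i, j][None, :, None, None] * \
                        xp[:, :, i * dilation: i * dilation + ho * stride: stride,
                           j * dilation: j * dilation + wo * stride: stride]
        cache = ("dw", xp)
    elif groups == 1:
        xp = _pad(xd, padding)
        win = _windows(xp, kh, kw, stride, dilation)
        ho, wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(
            n, cin * kh * kw, ho * wo)
        out = np.matmul(wd.reshape(cout, -1), cols).reshape(n, cout, ho, wo)
        cache = ("gemm", cols)
    else:
        xp = _pad(xd, padding)
        win = _windows(xp, kh, kw, stride, dilation)  # (N,Cin,Ho,Wo,kh,kw)
        ho, wo = win.shape[2], win.shape[3]
        wing = win.reshape(n, groups, cpg, ho, wo, kh, kw)
        wg = wd.reshape(groups, cout // groups, cpg, kh, kw)
        out = np.einsum("ngchwkl,gockl->ngohw", wing, wg, optimize=True).reshape(
            n, cout, ho, wo)
        cache = ("grouped", wing)

    if bd is not None:
        out = out + bd.reshape(1, cout, 1, 1)

    if not is_tensor:
        return out

    xt = x if isinstance(x, Tensor) else Tensor(xd)
    wt = weight if isinstance(weight, Tensor) else Tensor(wd)
    parents = [xt, wt]
    bt = None
    if bias is not None:
        bt = bias if isinstance(bias, Tensor) else Tensor(bd)
        parents.append(bt)

    def backward(g):
        gb = g.sum(axis=(0, 2, 3)) if bt is not None else None
        kind = cache[0]
        if kind == "pw":
            xr = cache[1]
            gr = g.reshape(n, cout, h * w)
            gw = np.einsum("nol,ncl->oc", gr, xr, optimize=True).reshape(wd.shape)
            gx = np.matmul(wd.reshape(cout, cin).T, gr).reshape(n, cin, h, w)
        elif kind == "dw":
            xp = cache[1]
            hog, wog = g.shape[-2:]
            gxp = np.zeros_like(xp)
            if _kernels.HAVE_NUMBA and g.dtype == np.float32 and xp.dtype == np.float32:
                gw3 = np.zeros((cin, kh, kw), dtype=wd.dtype)
                _kernels.dw_backward(_contig(xp), _contig(wd[:, 0]),
                                     _contig(g), gxp, gw3,
                                     stride, dilation)
                gw = gw3[:, None]
            else:
                gw = np.empty((cin, 1, kh, kw), dtype=wd.dtype)
                for i in range(kh):
                    for j in range(kw):
                        rows = slice(i * dilation, i * dilation + hog * stride, stride)
                        cols = slice(j * dilation, j * dilation + wog * stride, stride)
                        gw[:, 0, i, j] = np.einsum("nchw,nchw->c", g,
                                                   xp[:, :, rows, cols], optimize=True)
                        gxp[:, :, rows, cols] += g * wd[:, 0, i, j][None, :, None, None]
            gx = gxp[:, :, padding:-padding, padding:-padding] if padding else gxp
        elif kind == "gemm":
            cols = cache[1]
            gr = g.reshape(n, cout, ho * wo)
            gw = np.einsum("nol,ncl->oc", gr, cols, optimize=True).reshape(wd.shape)
            gcols = np.matmul(wd.reshape(cout, -1).T, gr)
            gwin = gcols.reshape(n, cin, kh, kw, ho, wo)
            gx = _scatter_windows(gwin, xd.shape, kh, kw, stride, padding, dilation)
        else:
            wing = cache[1]
            gg = g.reshape(n, groups, cout // groups, ho, wo)
            wg = wd.reshape(groups, cout // groups, cpg, kh, kw)
            gw = np.einsum("ngchwkl,ngohw->gockl", wing, gg, optimize=True).reshape(wd.shape)
            gwin = np.einsum("ngohw,gockl->ngchwkl", gg, wg, optimize=True).reshape(
                n, cin, ho, wo, kh, kw)
            gwin = gwin.transpose(0, 1, 4, 5, 2, 3)
            gx = _scatter_windows(gwin, xd.shape, kh, kw, stride, padding, dilation)
        grads = [gx.astype(xd.dtype, copy=False), gw.astype(wd.dtype, copy=False)]
        if bt is not None:
            grads.append(gb.astype(bd.dtype, copy=False))
        return tuple(grads)

    return Tensor._make(out, parents, backward)
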