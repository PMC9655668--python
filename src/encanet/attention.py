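"""Channel and spatial attention mechanisms for feature recalibration.

Implements the family of multiplicative attention gates used in the detector's
encoder stage:

* **SE** — squeeze (global average pooling to a per-channel descriptor) and
  excitation (bottleneck MLP ``C -> C/r -> C`` with ReLU inside and a sigmoid
  gate outside).
* **CAM** — the channel half of CBAM: one shared MLP applied to both the
  average-pooled and max-pooled descriptors, gates summed before the sigmoid.
* **ECA** — a 1-D convolution of adaptive odd kernel size over the
  average-pooled descriptor (no bias, no bottleneck).
* **ECAM** — the enhanced channel attention module: the max-pooled descriptor
  enters only through a sigmoid gate that multiplies the average-pooled
  descriptor, so a single MLP pass replaces CAM's two.
* **SAM** — spatial attention: channel-wise mean and max maps stacked and
  convolved with one ``k x k`` filter, sigmoided into a per-position gate.
* **CBAM / ECBAM** — channel stage (CAM / ECAM) followed sequentially by SAM.

All operators are pure functions of their inputs and weights.  They accept
plain numpy arrays (for closed-form checking) or autograd tensors (inside the
trainable network) interchangeably.  Feature maps are ``(N, C, H, W)``;
channel descriptors and gates are ``(N, C)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nnops import Module, Tensor, ops
from .nnops.conv import conv2d
from .nnops.layers import DTYPE

KINDS = ("none", "se", "eca", "cam", "ecam", "sam", "cbam", "ecbam")


# ---------------------------------------------------------------------------
# configuration and weight containers
# ---------------------------------------------------------------------------

@dataclass
class AttentionConfig:
    """Which attention mechanism to build and its hyperparameters.

    ``reduction`` is the bottleneck divisor r of the excitation MLP
    (``C -> C/r -> C``); ``spatial_kernel`` is the odd side of the spatial
    attention convolution.
    """

    kind: str = "ecbam"
    channels: int = 512
    reduction: int = 16
    spatial_kernel: int = 7
    mlp_bias: bool = True

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown attention kind {self.kind!r}; expected one of {KINDS}")
        if self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be odd")
        if self.kind in ("se", "cam", "ecam", "cbam", "ecbam") \
                and self.channels % self.reduction != 0:
            raise ValueError("reduction ratio must divide the channel count")


@dataclass
class MLPWeights:
    """Shared excitation MLP: ``P = sigmoid(W2 @ relu(W1 @ z + b1) + b2)``."""

    W1: np.ndarray  # (C/r, C)
    b1: np.ndarray  # (C/r,)
    W2: np.ndarray  # (C, C/r)
    b2: np.ndarray  # (C,)
    r: int = 16

    @classmethod
    def init(cls, channels: int, reduction: int = 16, rng=None, scale=None):
        if channels % reduction != 0:
            raise ValueError("reduction must divide channels")
        rng = rng or np.random.default_rng(0)
        hidden = channels // reduction
        s1 = scale if scale is not None else np.sqrt(2.0 / channels)
        s2 = scale if scale is not None else np.sqrt(2.0 / hidden)
        return cls(
            W1=rng.normal(0, s1, (hidden, channels)).astype(DTYPE),
            b1=np.zeros(hidden, dtype=DTYPE),
            W2=rng.normal(0, s2, (channels, hidden)).astype(DTYPE),
            b2=np.zeros(channels, dtype=DTYPE),
            r=reduction,
        )

    @property
    def channels(self) -> int:
        return self.W1.shape[1]

    def param_count(self) -> int:
        return sum(int(np.asarray(a if not isinstance(a, Tensor) else a.data).size)
                   for a in (self.W1, self.b1, self.W2, self.b2))


# ---------------------------------------------------------------------------
# pooling / descriptor operators
# ---------------------------------------------------------------------------

def _check_spatial(x):
    shape = ops.asarray(x).shape
    if len(shape) != 4:
        raise ValueError(f"expected a (N, C, H, W) feature map, got shape {shape}")
    if shape[2] == 0 or shape[3] == 0:
        raise ValueError("feature map has empty spatial extent")


def global_average_pool(x):
    """Squeeze: per-channel spatial mean, ``z_c = (1/HW) sum_ij x_c(i,j)``."""
    _check_spatial(x)
    return ops.mean(x, axis=(2, 3))


def global_max_pool(x):
    """Per-channel spatial maximum, ``m_c = max_ij x_c(i,j)``."""
    _check_spatial(x)
    return ops.amax(x, axis=(2, 3))


def _mlp(z, w: MLPWeights):
    # z: (N, C); weights stored row-major so the math is W1 @ z per sample
    h = ops.relu(ops.matmul(z, _t(w.W1)) + w.b1)
    return ops.matmul(h, _t(w.W2)) + w.b2


def _t(a):
    if isinstance(a, Tensor):
        return a.transpose((1, 0))
    return np.asarray(a).T


def se_excitation(z, w: MLPWeights):
    """Excitation: ``P = sigmoid(W2 relu(W1 z + b1) + b2)``, each gate in (0,1)."""
    zshape = ops.asarray(z).shape
    if zshape[-1] != w.channels:
        raise ValueError(f"descriptor length {zshape[-1]} != MLP width {w.channels}")
    return ops.sigmoid(_mlp(z, w))


def cam_attention(x, w: MLPWeights):
    """CBAM channel gate: shared MLP on both pooled descriptors, summed."""
    za = global_average_pool(x)
    zm = global_max_pool(x)
    if ops.asarray(za).shape[-1] != w.channels:
        raise ValueError("channel count does not match the MLP width")
    return ops.sigmoid(_mlp(za, w) + _mlp(zm, w))


def ecam_descriptor(x):
    """Enhanced descriptor ``z'_c = sigmoid(m_c) * z_c``.

    The max-pooled branch acts only through the sigmoid gate; no MLP is spent
    on it, which is the mechanism's saving over CAM.
    """
    return ops.sigmoid(global_max_pool(x)) * global_average_pool(x)


def ecam_attention(x, w: MLPWeights, gate_override=None):
    """ECAM gate: SE-style excitation of the enhanced descriptor.

    ``gate_override`` replaces ``sigmoid(m_c)`` (e.g. the constant 1 reduces
    the mechanism exactly to SE); it exists for analysis, not training.
    """
    if gate_override is not None:
        z = gate_override * global_average_pool(x)
    else:
        z = ecam_descriptor(x)
    return se_excitation(z, w)


def eca_kernel_size(channels: int) -> int:
    """Adaptive odd kernel size: nearest odd not above ``log2(C)/2 + 1/2``."""
    t = int((np.log2(channels) + 1) / 2)
    return t if t % 2 == 1 else t + 1


def eca_attention(x, kernel_weights):
    """ECA gate: 1-D convolution (no bias) over the avg-pooled descriptor."""
    k = int(np.asarray(ops.asarray(kernel_weights)).size)
    if k % 2 == 0:
        raise ValueError("ECA kernel size must be odd")
    z = global_average_pool(x)  # (N, C)
    n, c = ops.asarray(z).shape
    z4 = ops.reshape(z, (n, 1, 1, c))
    w4 = ops.reshape(kernel_weights, (1, 1, 1, k))
    out = conv2d(z4, w4, padding=0, stride=1) if k == 1 else _conv1d_padded(z4, w4, k)
    return ops.sigmoid(ops.reshape(out, (n, c)))


def _conv1d_padded(z4, w4, k):
    pad = (k - 1) // 2
    zd = z4 if isinstance(z4, Tensor) else np.asarray(z4)
    if isinstance(zd, Tensor):
        zeros = Tensor(np.zeros(zd.shape[:3] + (pad,), dtype=zd.data.dtype))
        zp = ops.concatenate([zeros, zd, zeros], axis=3)
    else:
        zp = np.pad(zd, ((0, 0), (0, 0), (0, 0), (pad, pad)))
    return conv2d(zp, w4)


def spatial_attention(t, conv_weight, conv_bias, kernel: int | None = None):
    """SAM gate: sigmoid of a ``k x k`` convolution of the stacked
    channel-wise mean and max maps.  Returns shape (N, 1, H, W)."""
    _check_spatial(t)
    w = conv_weight
    wshape = ops.asarray(w).shape
    if kernel is None:
        kernel = wshape[-1]
    if kernel % 2 == 0:
        raise ValueError("spatial attention kernel must be odd")
    if wshape != (1, 2, kernel, kernel):
        raise ValueError(f"spatial conv weight must be (1, 2, {kernel}, {kernel})")
    avg_map = ops.mean(t, axis=1, keepdims=True)
    max_map = ops.amax(t, axis=1, keepdims=True)
    stacked = ops.concatenate([avg_map, max_map], axis=1)
    out = conv2d(stacked, w, conv_bias, padding=(kernel - 1) // 2)
    return ops.sigmoid(out)


def apply_channel_attention(x, p):
    """Scale every channel map by its gate: ``o_c(i,j) = p_c * x_c(i,j)``."""
    _check_spatial(x)
    n, c = ops.asarray(p).shape
    if c != ops.asarray(x).shape[1]:
        raise ValueError("gate length does not match the channel count")
    return x * ops.reshape(p, (n, c, 1, 1))


def cbam_forward(x, mlp: MLPWeights, sam_weight, sam_bias):
    """CBAM: CAM channel gate, then spatial gate, applied sequentially."""
    t = apply_channel_attention(x, cam_attention(x, mlp))
    return t * spatial_attention(t, sam_weight, sam_bias)


def ecbam_forward(x, mlp: MLPWeights, sam_weight, sam_bias):
    """ECBAM: ECAM channel gate, then spatial gate, applied sequentially."""
    t = apply_channel_attention(x, ecam_attention(x, mlp))
    return t * spatial_attention(t, sam_weight, sam_bias)


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------

def attention_param_count(cfg: AttentionConfig) -> int:
    """Exact trainable-parameter count of a mechanism, by shape enumeration.

    The excitation MLP carries biases; the spatial conv carries a bias; the
    ECA conv does not.
    """
    c, r, k = cfg.channels, cfg.reduction, cfg.spatial_kernel
    mlp = 2 * c * (c // r) + (c // r) + c if cfg.mlp_bias else 2 * c * (c // r)
    sam = 2 * k * k + 1
    if cfg.kind == "none":
        return 0
    if cfg.kind in ("se", "cam", "ecam"):
        return mlp
    if cfg.kind == "eca":
        return eca_kernel_size(c)
    if cfg.kind == "sam":
        return sam
    if cfg.kind in ("cbam", "ecbam"):
        return mlp + sam
    raise ValueError(f"unknown attention kind {cfg.kind!r}")


# ---------------------------------------------------------------------------
# trainable module
# ---------------------------------------------------------------------------

class AttentionEncoder(Module):
    """Any configured attention mechanism as a trainable encoder layer.

    The forward pass routes through the pure operators above, so the module
    and the closed-form math cannot drift apart.
    """

    def __init__(self, cfg: AttentionConfig, rng=None):
        super().__init__()
        self.cfg = cfg
        rng = rng or np.random.default_rng(0)
        c, r, k = cfg.channels, cfg.reduction, cfg.spatial_kernel
        if cfg.kind in ("se", "cam", "ecam", "cbam", "ecbam"):
            init = MLPWeights.init(c, r, rng)
            self.mlp_w1 = Tensor(init.W1, requires_grad=True)
            self.mlp_b1 = Tensor(init.b1, requires_grad=True)
            self.mlp_w2 = Tensor(init.W2, requires_grad=True)
            self.mlp_b2 = Tensor(init.b2, requires_grad=True)
        if cfg.kind in ("sam", "cbam", "ecbam"):
            w = rng.normal(0, np.sqrt(2.0 / (2 * k * k)), (1, 2, k, k)).astype(DTYPE)
            self.sam_weight = Tensor(w, requires_grad=True)
            self.sam_bias = Tensor(np.zeros(1, dtype=DTYPE), requires_grad=True)
        if cfg.kind == "eca":
            ke = eca_kernel_size(c)
            self.eca_weight = Tensor(
                rng.normal(0, np.sqrt(1.0 / ke), ke).astype(DTYPE), requires_grad=True)

    @property
    def mlp(self) -> MLPWeights:
        return MLPWeights(self.mlp_w1, self.mlp_b1, self.mlp_w2, self.mlp_b2,
                          r=self.cfg.reduction)

    def forward(self, x):
        kind = self.cfg.kind
        if kind == "none":
            return x
        if kind == "se":
            return apply_channel_attention(x, se_excitation(global_average_pool(x), self.mlp))
        if kind == "cam":
            return apply_channel_attention(x, cam_attention(x, self.mlp))
        if kind == "ecam":
            return apply_channel_attention(x, ecam_attention(x, self.mlp))
        if kind == "eca":
            return apply_channel_attention(x, eca_attention(x, self.eca_weight))
        if kind == "sam":
            return x * spatial_attention(x, self.sam_weight, self.sam_bias)
        if kind == "cbam":
            return cbam_forward(x, self.mlp, self.sam_weight, self.sam_bias)
        if kind == "ecbam":
            return ecbam_forward(x, self.mlp, self.sam_weight, self.sam_bias)
        raise ValueError(f"unknown attention kind {kind!r}")
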