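"""Attention operators against scalar/loop oracles and closed-form cases."""

import numpy as np
import pytest
from scipy.special import expit

from encanet.attention import (AttentionConfig, AttentionEncoder, MLPWeights,
                               apply_channel_attention, attention_param_count,
                               cam_attention, eca_attention, eca_kernel_size,
                               ecam_attention, ecam_descriptor, ecbam_forward,
                               global_average_pool, global_max_pool,
                               se_excitation, spatial_attention)

# ---------------------------------------------------------------------------
# independent oracles: plain scalar loops, no vectorization
# ---------------------------------------------------------------------------


def loop_gap(x):
    n, c, h, w = x.shape
    out = np.zeros((n, c))
    for ni in range(n):
        for ci in range(c):
            s = 0.0
            for i in range(h):
                for j in range(w):
                    s += x[ni, ci, i, j]
            out[ni, ci] = s / (h * w)
    return out


def loop_gmp(x):
    n, c, h, w = x.shape
    out = np.full((n, c), -np.inf)
    for ni in range(n):
        for ci in range(c):
            for i in range(h):
                for j in range(w):
                    out[ni, ci] = max(out[ni, ci], x[ni, ci, i, j])
    return out


def loop_mlp_gate(z, w):
    n, c = z.shape
    hidden = w.W1.shape[0]
    out = np.zeros((n, c))
    for ni in range(n):
        h = np.zeros(hidden)
        for k in range(hidden):
            acc = w.b1[k]
            for ci in range(c):
                acc += w.W1[k, ci] * z[ni, ci]
            h[k] = max(acc, 0.0)
        for ci in range(c):
            acc = w.b2[ci]
            for k in range(hidden):
                acc += w.W2[ci, k] * h[k]
            out[ni, ci] = 1.0 / (1.0 + np.exp(-acc))
    return out


def loop_spatial(t, w, b, k):
    n, c, h, wd = t.shape
    pad = (k - 1) // 2
    out = np.zeros((n, 1, h, wd))
    for ni in range(n):
        avg = t[ni].mean(axis=0)
        mx = t[ni].max(axis=0)
        stacked = np.stack([avg, mx])
        for i in range(h):
            for j in range(wd):
                acc = b[0]
                for ch in range(2):
                    for di in range(k):
                        for dj in range(k):
                            ii, jj = i + di - pad, j + dj - pad
                            if 0 <= ii < h and 0 <= jj < wd:
                                acc += w[0, ch, di, dj] * stacked[ch, ii, jj]
                out[ni, 0, i, j] = 1.0 / (1.0 + np.exp(-acc))
    return out


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------


def test_global_average_pool_closed_form():
    x = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2)
    assert global_average_pool(x)[0, 0] == pytest.approx(2.5)
    const = np.full((2, 3, 4, 4), 7.25)
    assert np.allclose(global_average_pool(const), 7.25)


def test_global_average_pool_matches_loop_oracle(rng):
    x = rng.normal(size=(1, 512, 13, 13))
    np.testing.assert_allclose(global_average_pool(x), loop_gap(x), rtol=1e-6)


def test_global_max_pool(rng):
    x = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2)
    assert global_max_pool(x)[0, 0] == 4.0
    neg = -np.abs(rng.normal(size=(1, 3, 4, 4))) - 1
    np.testing.assert_allclose(global_max_pool(neg), loop_gmp(neg))
    x = rng.normal(size=(2, 6, 5, 7))
    np.testing.assert_allclose(global_max_pool(x), loop_gmp(x))


def test_empty_spatial_extent_rejected():
    with pytest.raises(ValueError, match="empty spatial"):
        global_average_pool(np.zeros((1, 2, 0, 3)))


# ---------------------------------------------------------------------------
# excitation MLPs
# ---------------------------------------------------------------------------


def zero_mlp(c, r):
    return MLPWeights(W1=np.zeros((c // r, c)), b1=np.zeros(c // r),
                      W2=np.zeros((c, c // r)), b2=np.zeros(c), r=r)


def test_se_excitation_zero_weights_give_half():
    w = zero_mlp(8, 2)
    z = np.arange(16, dtype=float).reshape(2, 8)
    np.testing.assert_array_equal(se_excitation(z, w), np.full((2, 8), 0.5))


def test_se_excitation_identity_mlp():
    w = MLPWeights(W1=np.eye(2), b1=np.zeros(2), W2=np.eye(2), b2=np.zeros(2), r=1)
    np.testing.assert_allclose(se_excitation(np.zeros((1, 2)), w), 0.5)


def test_se_excitation_matches_scalar_oracle(rng):
    w = MLPWeights.init(4, 2, rng=rng, scale=0.5)
    z = rng.normal(size=(3, 4))
    np.testing.assert_allclose(se_excitation(z, w), loop_mlp_gate(z, w), rtol=1e-6)


def test_se_excitation_shape_mismatch():
    with pytest.raises(ValueError, match="descriptor length"):
        se_excitation(np.zeros((1, 5)), zero_mlp(8, 2))


def test_cam_attention(feature_map, rng):
    c = feature_map.shape[1]
    assert np.all(cam_attention(feature_map, zero_mlp(c, 2)) == 0.5)
    # constant map: avg == max, so the gate is sigmoid(2 * MLP(c * ones))
    w = MLPWeights.init(c, 2, rng=rng, scale=0.3)
    const = np.full((1, c, 3, 3), 1.7)
    z = np.full((1, c), 1.7)
    h = np.maximum(z @ w.W1.T + w.b1, 0)
    expected = expit(2 * (h @ w.W2.T + w.b2))
    np.testing.assert_allclose(cam_attention(const, w), expected, rtol=1e-6)
    # random input against the scalar loop applied to both pooled branches
    za, zm = loop_gap(feature_map), loop_gmp(feature_map)
    pre_a = np.maximum(za @ w.W1.T + w.b1, 0) @ w.W2.T + w.b2
    pre_m = np.maximum(zm @ w.W1.T + w.b1, 0) @ w.W2.T + w.b2
    np.testing.assert_allclose(cam_attention(feature_map, w),
                               expit(pre_a + pre_m), rtol=1e-6)


# ---------------------------------------------------------------------------
# ECAM
# ---------------------------------------------------------------------------


def test_ecam_descriptor_closed_form():
    assert np.all(ecam_descriptor(np.zeros((1, 2, 3, 3))) == 0.0)
    ones = np.ones((1, 1, 4, 4))
    assert ecam_descriptor(ones)[0, 0] == pytest.approx(0.731059, abs=1e-6)
    x = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2)
    assert ecam_descriptor(x)[0, 0] == pytest.approx(2.455034, abs=1e-6)


def test_ecam_attention_zero_mlp(feature_map):
    c = feature_map.shape[1]
    assert np.all(ecam_attention(feature_map, zero_mlp(c, 2)) == 0.5)


def test_ecam_gate_forced_to_one_is_bitwise_se(feature_map, rng):
    """With the max-pool gate replaced by 1, ECAM must equal SE exactly."""
    c = feature_map.shape[1]
    w = MLPWeights.init(c, 4, rng=rng, scale=0.4)
    ecam = ecam_attention(feature_map, w, gate_override=1.0)
    se = se_excitation(global_average_pool(feature_map), w)
    np.testing.assert_array_equal(ecam, se)


def test_ecam_attention_composes_oracle_operations(feature_map, rng):
    c = feature_map.shape[1]
    w = MLPWeights.init(c, 2, rng=rng, scale=0.4)
    z = expit(loop_gmp(feature_map)) * loop_gap(feature_map)
    np.testing.assert_allclose(ecam_attention(feature_map, w),
                               loop_mlp_gate(z, w), rtol=1e-6)


def test_ecam_gate_monotone_in_max_descriptor():
    """For fixed positive average, the enhanced descriptor grows with the max."""
    z = 2.0
    values = [expit(m) * z for m in np.linspace(-5, 5, 21)]
    assert np.all(np.diff(values) > 0)


# ---------------------------------------------------------------------------
# ECA
# ---------------------------------------------------------------------------


def test_eca_attention_zero_weights(feature_map):
    assert np.all(eca_attention(feature_map, np.zeros(5)) == 0.5)


def test_eca_kernel_one_is_pointwise_sigmoid(feature_map):
    expected = expit(global_average_pool(feature_map))
    np.testing.assert_allclose(eca_attention(feature_map, np.ones(1)), expected,
                               rtol=1e-6)


def test_eca_even_kernel_rejected(feature_map):
    with pytest.raises(ValueError, match="odd"):
        eca_attention(feature_map, np.zeros(4))


def test_eca_adaptive_kernel_and_param_count():
    assert eca_kernel_size(512) == 5
    assert attention_param_count(AttentionConfig(kind="eca", channels=512)) == 5


# ---------------------------------------------------------------------------
# spatial attention
# ---------------------------------------------------------------------------


def test_spatial_attention_zero_weights(feature_map):
    out = spatial_attention(feature_map, np.zeros((1, 2, 7, 7)), np.zeros(1))
    assert out.shape == (4, 1, 5, 5)
    assert np.all(out == 0.5)


def test_spatial_attention_center_tap_identity(rng):
    """Single channel, center tap 1 on the avg branch -> sigmoid(t) pointwise."""
    t = rng.normal(size=(2, 1, 6, 6))
    w = np.zeros((1, 2, 7, 7))
    w[0, 0, 3, 3] = 1.0
    out = spatial_attention(t, w, np.zeros(1))
    np.testing.assert_allclose(out, expit(t), rtol=1e-6)


def test_spatial_attention_matches_loop_convolution(feature_map, rng):
    for k in (3, 7):
        w = rng.normal(size=(1, 2, k, k)) * 0.3
        b = rng.normal(size=1)
        out = spatial_attention(feature_map, w, b)
        np.testing.assert_allclose(out, loop_spatial(feature_map, w, b, k),
                                   atol=1e-5)


def test_spatial_attention_even_kernel_rejected(feature_map):
    with pytest.raises(ValueError, match="odd"):
        spatial_attention(feature_map, np.zeros((1, 2, 4, 4)), np.zeros(1))


# ---------------------------------------------------------------------------
# application and composition
# ---------------------------------------------------------------------------


def test_apply_channel_attention(feature_map, rng):
    n, c = feature_map.shape[:2]
    ones = np.ones((n, c))
    np.testing.assert_array_equal(apply_channel_attention(feature_map, ones),
                                  feature_map)
    assert np.all(apply_channel_attention(feature_map, np.zeros((n, c))) == 0)
    p = rng.uniform(0.1, 0.9, size=(n, c))
    out = apply_channel_attention(feature_map, p)
    for ni in range(n):
        for ci in range(c):
            np.testing.assert_allclose(out[ni, ci], p[ni, ci] * feature_map[ni, ci])
    with pytest.raises(ValueError, match="channel count"):
        apply_channel_attention(feature_map, np.ones((n, c + 1)))


def test_ecbam_zero_weights_scale_quarter(feature_map):
    c = feature_map.shape[1]
    out = ecbam_forward(feature_map, zero_mlp(c, 2), np.zeros((1, 2, 7, 7)),
                        np.zeros(1))
    np.testing.assert_allclose(out, 0.25 * feature_map, rtol=1e-6)


def test_ecbam_equals_two_stage_composition(feature_map, rng):
    c = feature_map.shape[1]
    w = MLPWeights.init(c, 2, rng=rng, scale=0.4)
    sw, sb = rng.normal(size=(1, 2, 7, 7)) * 0.2, rng.normal(size=1)
    t = apply_channel_attention(feature_map, ecam_attention(feature_map, w))
    expected = t * loop_spatial(t, sw, sb, 7)
    np.testing.assert_allclose(ecbam_forward(feature_map, w, sw, sb), expected,
                               atol=1e-6)


@pytest.mark.parametrize("kind", ["se", "eca", "cam", "ecam", "sam", "cbam", "ecbam"])
def test_shape_preservation_and_open_interval(kind, rng):
    cfg = AttentionConfig(kind=kind, channels=8, reduction=2, spatial_kernel=3)
    enc = AttentionEncoder(cfg, rng=rng)
    x = rng.normal(size=(3, 8, 6, 6)).astype(np.float32)
    out = enc(x)
    assert out.data.shape == x.shape
    assert np.all(np.isfinite(out.data))
    # the underlying gates are strict sigmoid outputs
    if kind in ("se", "cam", "ecam"):
        gate = {"se": lambda: se_excitation(global_average_pool(x), enc.mlp),
                "cam": lambda: cam_attention(x, enc.mlp),
                "ecam": lambda: ecam_attention(x, enc.mlp)}[kind]()
        gd = gate.data if hasattr(gate, "data") else gate
        assert np.all(gd > 0) and np.all(gd < 1)


def test_sigmoid_numerically_stable():
    from encanet.nnops import ops
    with np.errstate(over="raise"):
        big = ops.sigmoid(np.array([-1e4, -31.0, 31.0, 1e4]))
    assert np.all(big >= 0) and np.all(big <= 1)
    assert big[1] > 0 and big[2] < 1


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------


def test_attention_param_count_closed_forms():
    assert attention_param_count(
        AttentionConfig(kind="ecam", channels=512, reduction=16)) == 33_312
    assert attention_param_count(
        AttentionConfig(kind="sam", spatial_kernel=7)) == 99
    ecbam = attention_param_count(
        AttentionConfig(kind="ecbam", channels=512, reduction=16, spatial_kernel=7))
    assert ecbam == 33_411
    assert ecbam / 1e6 <= 0.04


@pytest.mark.parametrize("channels", [64, 512])
@pytest.mark.parametrize("kind", ["none", "se", "eca", "cam", "ecam", "sam",
                                  "cbam", "ecbam"])
def test_param_count_matches_instantiated_module(kind, channels):
    for r in (2, 4, 8, 16, 32):
        for k in (3, 5, 7, 9, 11):
            cfg = AttentionConfig(kind=kind, channels=channels, reduction=r,
                                  spatial_kernel=k)
            assert attention_param_count(cfg) == AttentionEncoder(cfg).param_count()
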