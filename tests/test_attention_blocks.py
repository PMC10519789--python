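"""Attention modules, the inverted-residual block and adaptive fusion.

The decisive checks are brute-force per-pixel oracles: each attention
variant is re-evaluated with explicit Python loops (no convolution
machinery) from the module's own weights, and the two must agree to
float32 tolerance."""

import numpy as np
import pytest

import fcaeffnet.autograd as ag
from fcaeffnet.autograd import Tensor
from fcaeffnet.blocks import (AdaptiveFusion, BlockConfig,
                              CoordinateAttention, FullConvCoordAttention,
                              MBConvBlock, SqueezeExcitation,
                              attention_mid_channels)


def _sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


def _swish(v):
    return v * _sigmoid(v)


def coord_attention_oracle(x, module, directional="pool"):
    """Loop-based evaluation of (full-conv) coordinate attention for one
    sample: directional aggregation, shared mid conv, two sigmoid gates,
    then the per-pixel product x * g_h(i) * g_w(j)."""
    c, h, w = x.shape
    mid = module.mid
    zh = np.zeros((c, h))
    zw = np.zeros((c, w))
    for ci in range(c):
        for i in range(h):
            if directional == "pool":
                zh[ci, i] = x[ci, i, :].mean()
            else:
                zh[ci, i] = sum(x[ci, i, j] * module.dir_h.weight.data[ci, 0, j]
                                for j in range(w))
        for j in range(w):
            if directional == "pool":
                zw[ci, j] = x[ci, :, j].mean()
            else:
                zw[ci, j] = sum(x[ci, i, j] * module.dir_w.weight.data[ci, i, 0]
                                for i in range(h))
    f_in = np.concatenate([zh, zw], axis=1)          # (c, h + w)
    wm = module.conv_mid.weight.data[:, :, 0, 0]
    f = _swish(np.array([[sum(wm[m, ci] * f_in[ci, t] for ci in range(c))
                          for t in range(h + w)] for m in range(mid)]))
    wh = module.conv_h.weight.data[:, :, 0, 0]
    ww = module.conv_w.weight.data[:, :, 0, 0]
    gh = _sigmoid(np.array([[sum(wh[ci, m] * f[m, i] for m in range(mid))
                             for i in range(h)] for ci in range(c)]))
    gw = _sigmoid(np.array([[sum(ww[ci, m] * f[m, h + j] for m in range(mid))
                             for j in range(w)] for ci in range(c)]))
    y = np.empty_like(x)
    for ci in range(c):
        for i in range(h):
            for j in range(w):
                y[ci, i, j] = x[ci, i, j] * gh[ci, i] * gw[ci, j]
    return y


class TestFullConvCoordAttention:
    @pytest.mark.parametrize("c,h,w", [(2, 4, 4), (4, 8, 8), (3, 5, 7)])
    def test_matches_per_pixel_oracle(self, rng, c, h, w):
        mod = FullConvCoordAttention(c, h, w, act="swish",
                                     rng=np.random.default_rng(1))
        mod.eval()
        x = rng.normal(0, 1, (1, c, h, w)).astype(np.float32)
        out = mod(Tensor(x)).numpy()[0]
        ref = coord_attention_oracle(x[0].astype(np.float64), mod,
                                     directional="conv")
        np.testing.assert_allclose(out, ref, atol=1e-4)

    def test_gates_open_halfway_with_zeroed_weights(self, rng):
        mod = FullConvCoordAttention(4, 6, 6)
        for _, p in mod.named_parameters():
            p.data[:] = 0.0
        x = rng.normal(0, 1, (2, 4, 6, 6)).astype(np.float32)
        out = mod(Tensor(x)).numpy()
        # sigmoid(0) = 0.5 on both gates: output is x / 4 exactly
        np.testing.assert_allclose(out, 0.25 * x, atol=1e-6)

    def test_output_strictly_gated(self, rng):
        mod = FullConvCoordAttention(3, 5, 5, rng=np.random.default_rng(2))
        x = rng.normal(0, 1, (2, 3, 5, 5)).astype(np.float32)
        out = mod(Tensor(x)).numpy()
        assert out.shape == x.shape
        ratio = np.abs(out) / np.maximum(np.abs(x), 1e-12)
        assert (ratio < 1.0).all()           # both gates lie strictly in (0, 1)

    def test_bound_to_build_resolution(self, rng):
        mod = FullConvCoordAttention(3, 6, 6)
        with pytest.raises(ValueError, match="directional kernels"):
            mod(Tensor(rng.normal(0, 1, (1, 3, 8, 8)).astype(np.float32)))

    def test_mid_width_rule(self):
        assert attention_mid_channels(1152) == 72
        assert attention_mid_channels(96) == 8     # floor engages
        assert attention_mid_channels(240) == 15


class TestCoordinateAttention:
    def test_matches_directional_pool_oracle(self, rng):
        mod = CoordinateAttention(3, act="swish", rng=np.random.default_rng(5))
        x = rng.normal(0, 1, (1, 3, 4, 6)).astype(np.float32)
        out = mod(Tensor(x)).numpy()[0]
        ref = coord_attention_oracle(x[0].astype(np.float64), mod,
                                     directional="pool")
        np.testing.assert_allclose(out, ref, atol=1e-4)


class TestSqueezeExcitation:
    def test_matches_loop_oracle(self, rng):
        mod = SqueezeExcitation(8, block_in_channels=8,
                                rng=np.random.default_rng(9))
        x = rng.normal(0, 1, (1, 8, 4, 4)).astype(np.float32)
        out = mod(Tensor(x)).numpy()[0]
        w1 = mod.reduce.weight.data[:, :, 0, 0]
        b1 = mod.reduce.bias.data
        w2 = mod.expand.weight.data[:, :, 0, 0]
        b2 = mod.expand.bias.data
        s = x[0].mean(axis=(1, 2))
        hid = _swish(w1 @ s + b1)
        gate = _sigmoid(w2 @ hid + b2)
        np.testing.assert_allclose(out, x[0] * gate[:, None, None], atol=1e-5)


class TestMBConvBlock:
    def _cfg(self, **kw):
        base = dict(in_channels=4, out_channels=4, expansion=6, kernel=3,
                    stride=1, attention="fca", drop_rate=0.2, in_resolution=8)
        base.update(kw)
        return BlockConfig(**base)

    def test_residual_identity_when_branch_dropped(self, rng):
        block = MBConvBlock(self._cfg(), norm="ln", act="gelu",
                            rng=np.random.default_rng(3))
        block.drop.force_drop = True
        x = rng.normal(0, 1, (2, 4, 8, 8)).astype(np.float32)
        out = block(Tensor(x)).numpy()
        assert np.array_equal(out, x)        # x + 0 * branch, exactly

    def test_stride_two_halves_resolution_without_residual(self, rng):
        block = MBConvBlock(self._cfg(stride=2, out_channels=8, in_resolution=8),
                            rng=np.random.default_rng(4))
        block.eval()
        x = rng.normal(0, 1, (2, 4, 8, 8)).astype(np.float32)
        out = block(Tensor(x)).numpy()
        assert out.shape == (2, 8, 4, 4)

    def test_parameter_count_matches_symbolic_hand_count(self):
        cfg = self._cfg()
        block = MBConvBlock(cfg)
        ce = 4 * 6
        mid = max(8, ce // 16)
        expected = (
            4 * ce + 2 * ce            # expansion conv + per-channel affine
            + ce * 9 + 2 * ce          # depthwise 3x3 + affine
            + ce * 8 + ce * 8          # directional (1,W) and (H,1) kernels
            + ce * mid                 # attention mid conv
            + 2 * mid * ce             # the two gate convs
            + ce * 4 + 2 * 4           # projection conv + affine
        )
        assert block.num_params() == expected

    def test_channel_mismatch_is_a_config_error(self, rng):
        block = MBConvBlock(self._cfg())
        with pytest.raises(ValueError):
            block(Tensor(rng.normal(0, 1, (1, 5, 8, 8)).astype(np.float32)))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            self._cfg(expansion=4)
        with pytest.raises(ValueError):
            self._cfg(stride=3)
        with pytest.raises(ValueError):
            self._cfg(drop_rate=1.0)


class TestAdaptiveFusion:
    def test_degenerates_to_each_branch(self, rng):
        af = AdaptiveFusion(3, 8, pool_factor=2, rng=np.random.default_rng(6))
        x = rng.normal(0, 1, (2, 3, 8, 8)).astype(np.float32)
        backbone = rng.normal(0, 1, (2, 8, 4, 4)).astype(np.float32)
        af.w1.data[:] = 0.0
        af.w2.data[:] = 1.0
        np.testing.assert_array_equal(af(Tensor(x), Tensor(backbone)).numpy(),
                                      backbone)
        af.w1.data[:] = 1.0
        af.w2.data[:] = 0.0
        pooled = af.proj(ag.max_pool2d(Tensor(x), 2)).numpy()
        np.testing.assert_array_equal(af(Tensor(x), Tensor(backbone)).numpy(),
                                      pooled)

    def test_equal_weights_match_pool_then_average_hand_computation(self, rng):
        af = AdaptiveFusion(1, 1, pool_factor=2)
        af.proj.weight.data[:] = 1.0         # identity 1x1 conv
        af.proj.bias.data[:] = 0.0
        af.w1.data[:] = 0.5
        af.w2.data[:] = 0.5
        x = rng.normal(0, 1, (1, 1, 4, 4)).astype(np.float32)
        backbone = rng.normal(0, 1, (1, 1, 2, 2)).astype(np.float32)
        out = af(Tensor(x), Tensor(backbone)).numpy()
        expected = np.empty((1, 1, 2, 2), np.float32)
        for i in range(2):
            for j in range(2):
                window_max = x[0, 0, 2 * i:2 * i + 2, 2 * j:2 * j + 2].max()
                expected[0, 0, i, j] = 0.5 * window_max + 0.5 * backbone[0, 0, i, j]
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_wrong_node_placement_raises(self, rng):
        af = AdaptiveFusion(3, 8, pool_factor=2)
        x = rng.normal(0, 1, (1, 3, 8, 8)).astype(np.float32)
        bad = rng.normal(0, 1, (1, 8, 2, 2)).astype(np.float32)
        with pytest.raises(ValueError, match="node placement"):
            af(Tensor(x), Tensor(bad))
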