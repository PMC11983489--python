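"""Algebra and shape contracts of the LCB, GMB and MSB blocks."""

import numpy as np
import pytest

from benet import nn
from benet.autograd import Tensor
from benet.blocks import GMB, HMB, LCB, MSB, mpb_forward
from benet.entropy_attention import sea_weights

from conftest import (cea_weights_oracle, conv2d_oracle, maxpool_same_oracle,
                      sea_weights_oracle)


def _finite_grads(module, loss):
    loss.backward()
    return all(p.grad is not None and np.isfinite(p.grad).all()
               for p in module.parameters())


class TestLCB:
    def test_zero_input_zero_output(self):
        nn.seed_init(0)
        block = LCB(2, 4)
        out = block(Tensor(np.zeros((1, 2, 16, 16), np.float32))).data
        # zero input stays zero through LoGC/convs (zero bias), BN and CEA
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_constant_input_with_zero_sum_log_kernel(self):
        nn.seed_init(0)
        block = LCB(1, 3, zero_sum=True)
        # uniform modulated weights: the effective kernel keeps the zero sum
        block.logc.weight.data = np.ones_like(block.logc.weight.data)
        x = Tensor(np.full((1, 1, 12, 12), 4.2, np.float32))
        y = block.logc(x).data
        assert np.allclose(y[:, :, 2:-2, 2:-2], 0.0, atol=1e-5)

    def test_output_is_pre_cea_map_scaled_by_oracle_weights(self, rng):
        nn.seed_init(1)
        block = LCB(4, 4).eval()
        x = Tensor(rng.standard_normal((1, 4, 16, 16)).astype(np.float32))
        out, pre = block(x, return_pre_cea=True)
        w = cea_weights_oracle(pre.data)
        assert np.all((w >= 0) & (w <= 1))
        assert np.allclose(out.data, pre.data * w[:, :, None, None], atol=1e-5)

    def test_spatial_size_preserved_and_differentiable(self, rng):
        nn.seed_init(2)
        block = LCB(2, 4)
        x = Tensor(rng.standard_normal((2, 2, 9, 13)).astype(np.float32))
        out = block(x)
        assert out.shape == (2, 4, 9, 13)
        assert _finite_grads(block, (out * out).mean())


class TestGMB:
    def test_zero_weights_give_zero_output(self):
        nn.seed_init(0)
        block = GMB(4)
        for p in block.parameters():
            p.data = np.zeros_like(p.data)
        x = Tensor(np.random.default_rng(0).standard_normal(
            (1, 4, 8, 8)).astype(np.float32))
        assert np.allclose(block(x, x).data, 0.0, atol=1e-7)

    def test_identity_mode_matches_tensor_arithmetic(self, rng):
        block = GMB(4, debug_identity=True)
        xs = rng.standard_normal((1, 4, 8, 8)).astype(np.float32)
        xd = rng.standard_normal((1, 4, 8, 8)).astype(np.float32)
        _, pre = block(Tensor(xs), Tensor(xd), return_pre_cea=True)
        cat = np.concatenate([xs, xd], axis=1)
        halves = [cat[:, i * 2:(i + 1) * 2] for i in range(4)]
        lifted = sum(np.concatenate([h, h], axis=1) for h in halves)
        assert np.allclose(pre.data, np.maximum(lifted, 0.0), atol=1e-6)

    def test_dilated_group_impulse_support(self):
        nn.seed_init(3)
        block = GMB(4)
        # group-1 conv has dilation 2: impulse response lives on {-2,0,2}^2
        w = np.zeros((1, 2, 9, 9), np.float32)
        w[0, 0, 4, 4] = 1.0
        resp = block.conv1(Tensor(w)).data[0, 0]
        nz = np.argwhere(np.abs(resp) > 1e-8) - 4
        assert set(map(tuple, nz)) <= {(a, b) for a in (-2, 0, 2)
                                       for b in (-2, 0, 2)}

    def test_not_symmetric_in_skip_and_decoder(self, rng):
        nn.seed_init(4)
        block = GMB(4).eval()
        xs = Tensor(rng.standard_normal((1, 4, 8, 8)).astype(np.float32))
        xd = Tensor(rng.standard_normal((1, 4, 8, 8)).astype(np.float32))
        assert not np.allclose(block(xs, xd).data, block(xd, xs).data,
                               atol=1e-5)

    def test_shape_mismatch_and_odd_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            GMB(3)
        block = GMB(4)
        a = Tensor(rng.standard_normal((1, 4, 8, 8)).astype(np.float32))
        b = Tensor(rng.standard_normal((1, 4, 4, 4)).astype(np.float32))
        with pytest.raises(ValueError):
            block(a, b)


class TestHMB:
    def test_cascade_consumes_previous_stage(self, rng):
        nn.seed_init(5)
        block = HMB(3).eval()
        # zero the first conv: its stage output (and everything fed to the
        # later stages) becomes the norm/activation of zero
        for attr in (block.convs[0].weight, block.convs[0].bias):
            attr.data = np.zeros_like(attr.data)
        x = Tensor(rng.standard_normal((1, 3, 10, 10)).astype(np.float32))
        out = block(x).data
        assert np.allclose(out, out[:, :, :1, :1], atol=1e-6)  # constant map

    def test_cascaded_receptive_field_is_13x13(self):
        nn.seed_init(6)
        block = HMB(1).eval()
        for conv in block.convs:
            conv.weight.data = np.abs(conv.weight.data) + 0.1
            conv.bias.data = np.zeros_like(conv.bias.data)
        x = np.zeros((1, 1, 31, 31), np.float32)
        x[0, 0, 15, 15] = 1.0
        out = block(Tensor(x)).data[0, 0]
        base = out[0, 0]  # response far from the impulse
        nz = np.argwhere(np.abs(out - base) > 1e-7)
        spread_y = nz[:, 0].max() - nz[:, 0].min() + 1
        spread_x = nz[:, 1].max() - nz[:, 1].min() + 1
        assert (spread_y, spread_x) == (13, 13)

    def test_zero_input_zero_biases_zero_output(self):
        nn.seed_init(7)
        block = HMB(2)
        out = block(Tensor(np.zeros((1, 2, 8, 8), np.float32))).data
        assert np.allclose(out, 0.0, atol=1e-7)


class TestMPB:
    def test_constant_map_squares(self):
        c = 0.37
        y = Tensor(np.full((1, 2, 9, 9), c, np.float32))
        assert np.allclose(mpb_forward(y).data, c * c, atol=1e-6)

    def test_single_peak_hand_evaluation(self):
        y = np.full((1, 1, 11, 11), 0.1, np.float32)
        y[0, 0, 5, 5] = 0.9
        w1 = mpb_forward(Tensor(y)).data[0, 0]
        assert w1[5, 5] == pytest.approx(0.81, abs=1e-6)
        # beyond Chebyshev distance 3 no pool window reaches the peak
        assert w1[0, 0] == pytest.approx(0.01, abs=1e-6)
        assert w1[5, 0] == pytest.approx(0.01, abs=1e-6)

    def test_bounded_by_squared_maximum(self, rng):
        y = Tensor(rng.uniform(0.01, 0.99, (1, 3, 12, 12)).astype(np.float32))
        w1 = mpb_forward(y).data
        assert w1.max() <= y.data.max() ** 2 + 1e-6

    def test_nested_pools_equal_direct_pools(self, rng):
        # the 5x5/7x7 pools are computed by nesting 3x3 filters; compare
        # with an independent per-pixel loop at each size
        y = rng.uniform(0, 1, (1, 2, 10, 10)).astype(np.float32)
        p3 = maxpool_same_oracle(y[0], 3)
        p5 = maxpool_same_oracle(y[0], 5)
        p7 = maxpool_same_oracle(y[0], 7)
        expected = y[0] * (p3 + p5 + p7) / 3.0
        assert np.allclose(mpb_forward(Tensor(y)).data[0], expected, atol=1e-6)


class TestMSB:
    def test_constant_unit_pyramid_combination(self):
        # stub the cascade so Y_hmb is exactly 1: W2 = 1 (uniform channels),
        # W1 = sigmoid(1)^2, output = 1 + W1 + W2 everywhere
        nn.seed_init(8)
        block = MSB(2)

        class _Identity(nn.Module):
            def forward(self, x):
                return x

        block.hmb = _Identity()
        x = Tensor(np.ones((1, 2, 8, 8), np.float32))
        out = block(x).data
        s1 = 1.0 / (1.0 + np.exp(-1.0))
        assert np.allclose(out, 1.0 + s1 * s1 + 1.0, atol=1e-5)

    def test_matches_straight_line_oracle(self, rng):
        nn.seed_init(9)
        block = MSB(2).eval()
        x = rng.standard_normal((1, 2, 8, 8)).astype(np.float32)
        out = block(Tensor(x)).data[0]

        # independent straight-line evaluation with the same weights
        cur = x[0].astype(float)
        stages = []
        for conv, bn, d in zip(block.hmb.convs, block.hmb.bns, (1, 2, 3)):
            z = conv2d_oracle(cur, conv.weight.data.astype(float),
                              conv.bias.data.astype(float), padding=d,
                              dilation=d)
            scale = bn.weight.data / np.sqrt(bn.running_var + bn.eps)
            shift = bn.bias.data - bn.running_mean * scale
            z = z * scale[:, None, None] + shift[:, None, None]
            cur = np.maximum(z, 0.0)
            stages.append(cur)
        y = stages[0] + stages[1] + stages[2]
        y_prime = 1.0 / (1.0 + np.exp(-y))
        pools = [maxpool_same_oracle(y_prime, k) for k in (3, 5, 7)]
        w1 = y_prime * (pools[0] + pools[1] + pools[2]) / 3.0
        w2 = sea_weights_oracle(y[None])[0]
        expected = (w1 + w2[None]) * y + y
        assert np.allclose(out, expected, atol=1e-5)

    def test_output_ratio_in_residual_band(self, rng):
        nn.seed_init(10)
        block = MSB(3).eval()
        x = Tensor(rng.standard_normal((1, 3, 12, 12)).astype(np.float32))
        y = block.hmb(x).data
        out = block(x).data
        mask = np.abs(y) > 1e-3
        ratio = out[mask] / y[mask]
        assert ratio.min() > 1.0 and ratio.max() < 3.0

    def test_requires_two_channels(self):
        with pytest.raises(ValueError):
            MSB(1)

    def test_spatial_size_preserved_and_differentiable(self, rng):
        nn.seed_init(11)
        block = MSB(2)
        x = Tensor(rng.standard_normal((1, 2, 8, 11)).astype(np.float32))
        out = block(x)
        assert out.shape == (1, 2, 8, 11)
        assert _finite_grads(block, (out * out).mean())
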