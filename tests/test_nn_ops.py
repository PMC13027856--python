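"""Convolution blocks, normalisations, attention, graph propagation,
pooling and the entropy penalty — checked against independent oracles and
by finite-difference gradients."""

import numpy as np
import pytest

from neurofuse.nn import ops
from neurofuse.nn.autodiff import Tensor


def conv3d_loop_oracle(x, w, b=None, stride=1, dilation=1):
    """Six-nested-loop reference convolution (same-padding)."""
    N, Cin, D, H, W = x.shape
    Cout, _, k, _, _ = w.shape
    p = dilation * (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    ek = (k - 1) * dilation + 1
    Do = (D + 2 * p - ek) // stride + 1
    Ho = (H + 2 * p - ek) // stride + 1
    Wo = (W + 2 * p - ek) // stride + 1
    out = np.zeros((N, Cout, Do, Ho, Wo))
    for n in range(N):
        for co in range(Cout):
            for d in range(Do):
                for h in range(Ho):
                    for ww in range(Wo):
                        acc = 0.0
                        for ci in range(Cin):
                            for a in range(k):
                                for bb in range(k):
                                    for c in range(k):
                                        acc += (
                                            xp[n, ci,
                                               d * stride + a * dilation,
                                               h * stride + bb * dilation,
                                               ww * stride + c * dilation]
                                            * w[co, ci, a, bb, c]
                                        )
                        out[n, co, d, h, ww] = acc + (0 if b is None else b[co])
    return out


class TestConv3d:
    def test_identity_kernel(self, rng):
        x = rng.random((1, 1, 5, 5, 5))
        w = np.zeros((1, 1, 3, 3, 3))
        w[0, 0, 1, 1, 1] = 1.0
        out = ops.conv3d(x, w).data
        assert np.abs(out - x).max() < 1e-12

    def test_all_ones_kernel_interior_sum(self):
        x = np.ones((1, 1, 5, 5, 5))
        w = np.ones((1, 1, 3, 3, 3))
        out = ops.conv3d(x, w).data
        assert out[0, 0, 2, 2, 2] == pytest.approx(27.0)

    @pytest.mark.parametrize("stride,dilation", [(1, 1), (2, 1), (1, 2)])
    def test_matches_nested_loop_oracle(self, rng, stride, dilation):
        for _ in range(5):
            x = rng.standard_normal((1, 2, 5, 5, 5))
            w = rng.standard_normal((2, 2, 3, 3, 3))
            b = rng.standard_normal(2)
            mine = ops.conv3d(x, w, b, stride=stride, dilation=dilation).data
            orc = conv3d_loop_oracle(x, w, b, stride=stride, dilation=dilation)
            assert np.abs(mine - orc).max() < 1e-10

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="channel"):
            ops.conv3d(rng.random((1, 2, 4, 4, 4)),
                       rng.random((1, 3, 3, 3, 3)))


class TestDilatedConv3d:
    def test_d1_equals_plain_conv(self, rng):
        x = rng.standard_normal((1, 1, 6, 6, 6))
        w = rng.standard_normal((1, 1, 3, 3, 3))
        a = ops.dilated_conv3d(x, w, 1).data
        b = ops.conv3d(x, w).data
        assert np.array_equal(a, b)

    def test_equals_zero_inflated_kernel(self, rng):
        """d=2 dilation equals a plain convolution with a zero-inflated
        5x5x5 kernel."""
        x = rng.standard_normal((1, 1, 7, 7, 7))
        w = rng.standard_normal((1, 1, 3, 3, 3))
        w_inflated = np.zeros((1, 1, 5, 5, 5))
        w_inflated[0, 0, ::2, ::2, ::2] = w[0, 0]
        a = ops.dilated_conv3d(x, w, 2).data
        b = ops.conv3d(x, w_inflated).data
        assert np.abs(a - b).max() < 1e-12

    def test_impulse_response_support(self):
        """Receptive field is (k-1)d + 1 per axis."""
        k, d = 3, 2
        x = np.zeros((1, 1, 11, 11, 11))
        x[0, 0, 5, 5, 5] = 1.0
        w = np.ones((1, 1, k, k, k))
        out = ops.dilated_conv3d(x, w, d).data[0, 0]
        support = np.argwhere(out != 0)
        span = support.max(axis=0) - support.min(axis=0) + 1
        assert np.all(span == (k - 1) * d + 1)


class TestSpectralNormalize:
    def test_sigma_one_after_normalization(self, rng):
        w = rng.standard_normal((4, 3, 3, 3, 3)) * 2.0
        w_hat, _ = ops.spectral_normalize(w)
        sigma = np.linalg.svd(w_hat.data.reshape(4, -1), compute_uv=False)[0]
        assert sigma == pytest.approx(1.0, abs=1e-3)

    def test_scale_invariance(self, rng):
        w = rng.standard_normal((3, 8))
        a, _ = ops.spectral_normalize(w)
        b, _ = ops.spectral_normalize(5.0 * w)
        assert np.abs(a.data - b.data).max() < 1e-6

    def test_orthogonal_unchanged(self):
        q, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((4, 4)))
        w_hat, _ = ops.spectral_normalize(q)
        assert np.abs(w_hat.data - q).max() < 1e-4

    def test_zero_kernel_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="zero"):
            w_hat, _ = ops.spectral_normalize(np.zeros((2, 5)))
        assert np.all(w_hat.data == 0)


class TestStatNormalize:
    def test_unit_moments(self, rng):
        x = rng.random((2, 3, 4, 4, 4)) * 7 + 2
        out = ops.stat_normalize(x, np.ones(3), np.zeros(3), eps=1e-12).data
        mu = out.mean(axis=(2, 3, 4))
        var = out.var(axis=(2, 3, 4))
        assert np.abs(mu).max() < 1e-6
        assert np.abs(var - 1).max() < 1e-4

    def test_two_voxel_hand_case(self):
        x = np.zeros((1, 1, 2, 1, 1))
        x[0, 0, :, 0, 0] = [0.0, 2.0]
        out = ops.stat_normalize(x, np.ones(1), np.zeros(1), eps=1e-15).data
        assert np.allclose(out[0, 0, :, 0, 0], [-1.0, 1.0], atol=1e-6)

    def test_beta_shifts_mean(self, rng):
        x = rng.random((1, 2, 3, 3, 3))
        out = ops.stat_normalize(x, np.ones(2), np.array([1.5, -2.0])).data
        assert out[0, 0].mean() == pytest.approx(1.5, abs=1e-6)
        assert out[0, 1].mean() == pytest.approx(-2.0, abs=1e-6)

    def test_constant_channel_stabilized(self):
        x = np.full((1, 1, 3, 3, 3), 4.0)
        out = ops.stat_normalize(x, np.ones(1), np.zeros(1)).data
        assert np.all(np.isfinite(out))


class TestResidualFuse:
    def test_zero_block_passes_previous(self, rng):
        f_prev = rng.random((1, 2, 4, 4, 4))
        phi = np.zeros((2, 2, 1, 1, 1))
        phi[0, 0, 0, 0, 0] = 1.0
        phi[1, 1, 0, 0, 0] = 1.0  # identity 1x1x1 conv
        out = ops.residual_fuse(np.zeros_like(f_prev), f_prev, phi).data
        assert np.abs(out - f_prev).max() < 1e-12

    def test_zero_phi_passes_block(self, rng):
        f_l = rng.random((1, 2, 4, 4, 4))
        out = ops.residual_fuse(f_l, rng.random((1, 2, 4, 4, 4)),
                                np.zeros((2, 2, 1, 1, 1))).data
        assert np.array_equal(out, f_l)

    def test_channel_alignment_32_to_64(self, rng):
        f_prev = rng.random((1, 32, 2, 2, 2))
        f_l = rng.random((1, 64, 2, 2, 2))
        phi = rng.random((64, 32, 1, 1, 1))
        assert ops.residual_fuse(f_l, f_prev, phi).shape == (1, 64, 2, 2, 2)


class TestChannelAttention:
    def test_identical_channels_uniform_weights(self):
        x = np.tile(np.random.default_rng(0).random((1, 1, 3, 3, 3)),
                    (1, 4, 1, 1, 1))
        w = np.ones((4, 4))
        _, alpha = ops.channel_attention(x, w, return_weights=True)
        assert np.allclose(alpha.data, 0.25)

    def test_weights_on_simplex(self, rng):
        x = rng.standard_normal((3, 5, 2, 2, 2))
        w = rng.standard_normal((5, 5))
        _, alpha = ops.channel_attention(x, w, return_weights=True)
        assert np.abs(alpha.data.sum(axis=1) - 1).max() < 1e-9
        assert np.all(alpha.data > 0)

    def test_dominant_channel_saturates(self, rng):
        x = rng.standard_normal((1, 3, 2, 2, 2))
        g = x.mean(axis=(2, 3, 4))[0]
        # craft w so channel 1's logit is +10 above the others
        w = np.zeros((3, 3))
        w[1] = 10.0 * g / (g @ g)
        _, alpha = ops.channel_attention(x, w, return_weights=True)
        assert alpha.data[0, 1] >= 0.999


class TestSpatialAttention:
    def test_zero_logits_halve_features(self, rng):
        x = rng.random((1, 2, 3, 3, 3))
        out = ops.spatial_attention(x, np.zeros((1, 3, 3, 3))).data
        assert np.abs(out - 0.5 * x).max() < 1e-12

    def test_large_logits_leave_unchanged(self, rng):
        x = rng.random((1, 2, 3, 3, 3))
        out = ops.spatial_attention(x, np.full((1, 3, 3, 3), 50.0)).data
        assert np.abs(out - x).max() < 1e-9

    def test_mask_strictly_in_unit_interval(self, rng):
        _, mask = ops.spatial_attention(
            rng.random((1, 1, 2, 2, 2)),
            rng.standard_normal((1, 2, 2, 2)), return_mask=True,
        )
        assert np.all(mask.data > 0) and np.all(mask.data < 1)


class TestGraphPropagate:
    def test_identity_propagation(self):
        H = np.abs(np.random.default_rng(0).random((3, 4)))
        out = ops.graph_propagate(H, np.eye(3), np.eye(4)).data
        assert np.abs(out - H).max() < 1e-12

    def test_two_node_chain_hand_case(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        H = np.eye(2)
        out = ops.graph_propagate(H, A, np.eye(2), activation="identity").data
        assert np.array_equal(out, A)

    def test_zero_adjacency_zero_output(self, rng):
        out = ops.graph_propagate(rng.random((4, 3)), np.zeros((4, 4)),
                                  rng.random((3, 3)),
                                  activation="identity").data
        assert np.all(out == 0)


class TestGlobalAvgPoolAndEntropy:
    def test_constant_map(self):
        x = np.full((1, 3, 2, 2, 2), 1.7)
        assert np.allclose(ops.global_avg_pool(x).data, 1.7)

    def test_one_hot_voxel(self):
        x = np.zeros((1, 1, 4, 4, 4))
        x[0, 0, 1, 2, 3] = 8.0
        assert ops.global_avg_pool(x).data[0, 0] == pytest.approx(8.0 / 64)

    def test_linearity(self, rng):
        f, g = rng.random((1, 2, 3, 3, 3)), rng.random((1, 2, 3, 3, 3))
        lhs = ops.global_avg_pool(2.0 * f + 3.0 * g).data
        rhs = 2.0 * ops.global_avg_pool(f).data + 3.0 * ops.global_avg_pool(g).data
        assert np.abs(lhs - rhs).max() < 1e-12

    def test_uniform_entropy_is_log_d(self):
        assert ops.entropy_penalty(np.zeros(4)).data == pytest.approx(
            np.log(4), abs=1e-9
        )

    def test_degenerate_entropy_near_zero(self):
        z = np.zeros(4)
        z[0] = 30.0
        assert ops.entropy_penalty(z).data <= 1e-9

    def test_entropy_bounds_over_random_draws(self, rng):
        for _ in range(1000):
            z = rng.standard_normal(5) * rng.uniform(0.1, 10)
            h = float(ops.entropy_penalty(z).data)
            assert -1e-12 <= h <= np.log(5) + 1e-12


class TestGradients:
    """Finite-difference checks tie the backward pass to the forward."""

    def check(self, fn, x0, eps=1e-6, tol=1e-4):
        x = Tensor(x0, requires_grad=True)
        out = fn(x)
        out.backward()
        i = tuple(np.unravel_index(np.argmax(np.abs(x.grad)), x0.shape))
        x_pert = x0.copy()
        x_pert[i] += eps
        num = (float(fn(Tensor(x_pert)).data) - float(out.data)) / eps
        assert x.grad[i] == pytest.approx(num, rel=tol, abs=1e-6)

    def test_stat_normalize_grad(self, rng):
        g, b = np.ones(2), np.zeros(2)
        self.check(
            lambda t: (ops.stat_normalize(t, g, b) ** 2).sum(),
            rng.standard_normal((1, 2, 3, 3, 3)),
        )

    def test_channel_attention_grad(self, rng):
        w = rng.standard_normal((3, 3))
        self.check(
            lambda t: (ops.channel_attention(t, w) ** 2).sum(),
            rng.standard_normal((1, 3, 2, 2, 2)),
        )

    def test_entropy_grad(self, rng):
        self.check(lambda t: ops.entropy_penalty(t), rng.standard_normal(6))
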