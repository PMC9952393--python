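"""Autodiff engine and network building blocks."""

import numpy as np
import pytest

from handpose.nn import (
    Tensor,
    concat,
    smooth_l1_elem,
    Conv2d,
    BatchNorm2d,
    SEResidual,
    Hourglass,
    ModelConfig,
    PoseNet,
    save_checkpoint,
    load_checkpoint,
    integrate_graph,
    normalize_attention_graph,
)
from handpose.codec import encode_dense, normalize_attention


def _numeric_grad(f, x, eps=1e-3):
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g


def _check_op(make_scalar, params, rtol=2e-2, atol=2e-3):
    out = make_scalar()
    for p in params:
        p.zero_grad()
    out.backward()
    for p in params:
        num = _numeric_grad(lambda: float(make_scalar().data), p.data)
        np.testing.assert_allclose(p.grad, num, rtol=rtol, atol=atol)


class TestAutodiff:
    def test_arithmetic_and_broadcast_grads(self):
        rng = np.random.default_rng(0)
        a = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
        b = Tensor(rng.normal(size=(4,)), requires_grad=True)
        _check_op(lambda: ((a * b + a / 2.0 - b).sigmoid().relu()).sum(), [a, b])

    def test_matmul_grad(self):
        rng = np.random.default_rng(1)
        a = Tensor(rng.normal(size=(3, 5)), requires_grad=True)
        b = Tensor(rng.normal(size=(5, 2)), requires_grad=True)
        _check_op(lambda: (a.matmul(b) * a.matmul(b)).mean(), [a, b])

    def test_conv2d_grad(self):
        rng = np.random.default_rng(2)
        x = Tensor(rng.normal(size=(2, 3, 6, 6)), requires_grad=True)
        w = Tensor(rng.normal(size=(4, 3, 3, 3)) * 0.5, requires_grad=True)
        bias = Tensor(rng.normal(size=4), requires_grad=True)
        def scalar():
            y = x.conv2d(w, bias, stride=2, pad=1)
            return (y * y).mean()
        _check_op(scalar, [x, w, bias])

    def test_maxpool_upsample_grads(self):
        rng = np.random.default_rng(3)
        x = Tensor(rng.normal(size=(2, 2, 4, 4)), requires_grad=True)
        _check_op(lambda: (x.maxpool2().upsample2() * x).sum(), [x])

    def test_concat_grad(self):
        rng = np.random.default_rng(4)
        a = Tensor(rng.normal(size=(1, 2, 3, 3)), requires_grad=True)
        b = Tensor(rng.normal(size=(1, 3, 3, 3)), requires_grad=True)
        _check_op(lambda: (concat([a, b], axis=1) * concat([a, b], axis=1)).sum(), [a, b])

    def test_smooth_l1_grad_and_values(self):
        x = Tensor(np.array([0.0, 0.5, 2.0, -2.0]), requires_grad=True)
        y = smooth_l1_elem(x, 1.0)
        np.testing.assert_allclose(y.data, [0.0, 0.125, 1.5, 1.5])
        y.sum().backward()
        np.testing.assert_allclose(x.grad, [0.0, 0.5, 1.0, -1.0])

    def test_backward_requires_scalar(self):
        x = Tensor(np.ones((2, 2)), requires_grad=True)
        with pytest.raises(ValueError, match="scalar"):
            (x * 2).backward()


class TestBlocks:
    def test_batchnorm_normalizes_and_grads(self):
        rng = np.random.default_rng(5)
        bn = BatchNorm2d(3)
        x = Tensor(rng.normal(2.0, 3.0, size=(4, 3, 5, 5)), requires_grad=True)
        y = bn(x)
        assert np.abs(y.data.mean(axis=(0, 2, 3))).max() < 1e-5
        np.testing.assert_allclose(y.data.std(axis=(0, 2, 3)), 1.0, atol=1e-3)
        y.mean().backward()
        assert bn.gamma.grad is not None and bn.beta.grad is not None

    def test_batchnorm_eval_uses_running_stats(self):
        rng = np.random.default_rng(6)
        bn = BatchNorm2d(2)
        x = rng.normal(1.0, 2.0, size=(8, 2, 4, 4))
        for _ in range(50):
            bn(Tensor(x))
        bn.eval()
        y1 = bn(Tensor(x[:2]))
        y2 = bn(Tensor(x[:2]))
        np.testing.assert_array_equal(y1.data, y2.data)

    def test_se_residual_identity_when_branch_zero(self):
        rng = np.random.default_rng(7)
        block = SEResidual(8, rng=rng)
        block.conv2.weight.data[:] = 0.0
        block.conv2.bias.data[:] = 0.0
        x = Tensor(rng.normal(size=(2, 8, 6, 6)).astype(np.float32))
        np.testing.assert_allclose(block(x).data, x.data, atol=1e-6)

    def test_se_gate_forced_to_one_is_plain_residual(self):
        rng = np.random.default_rng(8)
        block = SEResidual(8, rng=rng)
        x = Tensor(rng.normal(size=(1, 8, 6, 6)).astype(np.float32))
        block.force_gate = 1.0
        plain = block(x).data
        # Manual plain residual through the same convs
        h = block.conv1(block.bn1(x).relu())
        h = block.conv2(block.bn2(h).relu())
        np.testing.assert_allclose(plain, x.data + h.data, atol=1e-6)

    def test_se_residual_channel_mismatch(self):
        block = SEResidual(8)
        with pytest.raises(ValueError, match="channels"):
            block(Tensor(np.zeros((1, 4, 6, 6))))

    @pytest.mark.parametrize("depth,size", [(1, 8), (3, 16), (4, 16)])
    def test_hourglass_shape_preserving(self, depth, size):
        hg = Hourglass(8, depth, rng=np.random.default_rng(9))
        x = Tensor(np.random.default_rng(0).normal(size=(1, 8, size, size)).astype(np.float32))
        assert hg(x).shape == x.shape

    def test_hourglass_indivisible_size_rejected(self):
        hg = Hourglass(8, 3, rng=np.random.default_rng(9))
        with pytest.raises(ValueError, match="divisible"):
            hg(Tensor(np.zeros((1, 8, 12, 12))))

    def test_hourglass_gradient_reaches_every_parameter(self):
        hg = Hourglass(8, 2, rng=np.random.default_rng(10))
        x = Tensor(np.random.default_rng(1).normal(size=(1, 8, 8, 8)).astype(np.float32))
        (hg(x) * hg(x)).mean().backward()
        for p in hg.parameters():
            assert p.grad is not None and np.isfinite(p.grad).all()


class TestPoseNet:
    @pytest.mark.parametrize(
        "out_size,C,stages,depth",
        [(64, 16, 1, 3), (64, 32, 2, 3), (128, 128, 2, 4)],
    )
    def test_shape_contracts(self, out_size, C, stages, depth):
        cfg = ModelConfig(J=5, C=C, stages=stages, hourglass_depth=depth, out_size=out_size)
        net = PoseNet(cfg, seed=0).eval()
        hd = out_size // 2
        rng = np.random.default_rng(0)
        imgs = rng.uniform(-1, 1, (2, out_size, out_size))
        pts = rng.uniform(-1, 1, (2, hd * hd, 3))
        mask = np.ones((2, hd * hd), bool)
        out = net(imgs, pts, mask)
        assert len(out.stages) == stages
        for st_out in out.stages:
            assert st_out.S.shape == (2, 5, hd, hd)
            assert st_out.V.shape == (2, 15, hd, hd)
            assert st_out.G.shape == (2, 5, hd, hd)
            assert st_out.H.shape == (2, 5, hd, hd)
            assert st_out.Q.shape == (2, C, hd, hd)
            # sigmoid range (float32 may saturate to the closed endpoints)
            assert np.all(st_out.S.data >= 0) and np.all(st_out.S.data <= 1)
            assert np.all(st_out.G.data >= 0) and np.all(st_out.G.data <= 1)
        assert out.keypoints.shape == (2, 5, 3)

    def test_wrong_input_size_rejected(self):
        cfg = ModelConfig(J=2, C=16, stages=1, hourglass_depth=3, out_size=64)
        net = PoseNet(cfg, seed=0)
        with pytest.raises(ValueError, match="64"):
            net(np.zeros((1, 32, 32)), np.zeros((1, 256, 3)), np.ones((1, 256), bool))

    def test_deterministic_inference(self):
        cfg = ModelConfig(J=3, C=16, stages=2, hourglass_depth=2, out_size=32)
        net = PoseNet(cfg, seed=1).eval()
        rng = np.random.default_rng(2)
        imgs = rng.uniform(-1, 1, (1, 32, 32))
        pts = rng.uniform(-1, 1, (1, 256, 3))
        mask = np.ones((1, 256), bool)
        a = net(imgs, pts, mask).keypoints.data
        b = net(imgs, pts, mask).keypoints.data
        np.testing.assert_array_equal(a, b)

    def test_predictions_inside_convex_hull_of_votes(self):
        # normalized attention makes every keypoint a convex combination of
        # the per-pixel votes, so predictions stay inside the vote cloud
        cfg = ModelConfig(J=4, C=16, stages=2, hourglass_depth=2, out_size=32)
        net = PoseNet(cfg, seed=3).eval()
        rng = np.random.default_rng(4)
        imgs = rng.uniform(-1, 1, (2, 32, 32))
        pts = rng.uniform(-1, 1, (2, 256, 3))
        mask = np.ones((2, 256), bool)
        out = net(imgs, pts, mask)
        kp = out.keypoints.data
        assert np.isfinite(kp).all()
        last = out.stages[-1]
        s = last.S.data.reshape(2, 4, -1)
        v = last.V.data.reshape(2, 4, 3, -1)
        votes = (cfg.theta * s - cfg.theta)[:, :, None, :] * v + pts.transpose(0, 2, 1)[:, None]
        for ax in range(3):
            assert np.all(kp[..., ax] <= votes[:, :, ax, :].max(axis=-1) + 1e-5)
            assert np.all(kp[..., ax] >= votes[:, :, ax, :].min(axis=-1) - 1e-5)

    def test_single_stage_uses_stage_one(self):
        cfg = ModelConfig(J=2, C=16, stages=1, hourglass_depth=2, out_size=32)
        net = PoseNet(cfg, seed=5)
        assert not hasattr(net, "hg2")
        out = net(np.zeros((1, 32, 32)), np.zeros((1, 256, 3)), np.ones((1, 256), bool))
        assert len(out.stages) == 1

    def test_oracle_injection_recovers_keypoints(self):
        """Feeding ground-truth S, V and support-confined attention through
        the in-graph integration reproduces the keypoints."""
        rng = np.random.default_rng(6)
        pts = rng.uniform(-1, 1, (300, 3))
        keys = pts[rng.integers(0, 300, 4)] + rng.normal(0, 0.05, (4, 3))
        t = encode_dense(keys, pts, theta=0.64)
        assert t.support.any(axis=1).all()
        H = normalize_attention(t.S)
        s = Tensor(t.S[None].astype(np.float32))
        v = Tensor(np.transpose(t.V, (0, 2, 1))[None].reshape(1, 12, -1).astype(np.float32))
        h = Tensor(H[None].astype(np.float32))
        rec = integrate_graph(s, v, h, pts[None], 0.64)
        assert np.abs(rec.data[0] - keys).max() < 1e-5   # float32 graph

    def test_attention_normalization_graph_matches_reference(self):
        rng = np.random.default_rng(7)
        H = rng.normal(size=(2, 3, 40)).astype(np.float32)
        mask = rng.uniform(size=(2, 40)) > 0.2
        out = normalize_attention_graph(Tensor(H, requires_grad=True), mask)
        for b in range(2):
            ref = normalize_attention(H[b].astype(np.float64), mask[b])
            np.testing.assert_allclose(out.data[b], ref, atol=1e-5)

    def test_checkpoint_round_trip_bit_exact(self, tmp_path):
        cfg = ModelConfig(J=2, C=16, stages=2, hourglass_depth=2, out_size=32)
        net = PoseNet(cfg, seed=8)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, net)
        net2 = load_checkpoint(path)
        assert net2.cfg == cfg
        s1, s2 = net.named_state(), net2.named_state()
        assert s1.keys() == s2.keys()
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])


class TestSoftAggregation:
    def _net(self):
        cfg = ModelConfig(J=2, C=16, stages=2, hourglass_depth=2, out_size=32)
        return PoseNet(cfg, seed=9), cfg

    def test_identity_configuration(self):
        net, cfg = self._net()
        agg = net.agg
        for conv in (agg.conv_a, agg.conv_b, agg.conv_c):
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        agg.beta.data[:] = 1.0
        rng = np.random.default_rng(0)
        i1 = Tensor(rng.normal(size=(1, 16, 16, 16)).astype(np.float32))
        f1 = Tensor(rng.normal(size=(1, 16, 16, 16)).astype(np.float32))
        v1 = Tensor(rng.normal(size=(1, 6, 16, 16)).astype(np.float32))
        h1 = Tensor(rng.normal(size=(1, 2, 16, 16)).astype(np.float32))
        np.testing.assert_array_equal(agg(i1, f1, v1, h1).data, i1.data)
        agg.beta.data[:] = 0.0
        np.testing.assert_array_equal(agg(i1, f1, v1, h1).data, 0.0)

    def test_linearity_in_input_with_zero_biases(self):
        net, _ = self._net()
        agg = net.agg
        agg.conv_a.bias.data[:] = 0.0
        rng = np.random.default_rng(1)
        i1 = Tensor(rng.normal(size=(1, 16, 16, 16)).astype(np.float32))
        zero = Tensor(np.zeros((1, 16, 16, 16), np.float32))
        v1 = Tensor(np.zeros((1, 6, 16, 16), np.float32))
        h1 = Tensor(np.zeros((1, 2, 16, 16), np.float32))
        base = agg(zero, zero, v1, h1).data         # constant terms
        one = agg(i1, zero, v1, h1).data - base
        two = agg(i1 * 2.0, zero, v1, h1).data - base
        np.testing.assert_allclose(two, 2.0 * one, rtol=1e-4, atol=1e-4)

    def test_gradients_reach_alpha_and_beta(self):
        net, cfg = self._net()
        rng = np.random.default_rng(2)
        imgs = rng.uniform(-1, 1, (1, 32, 32))
        pts = rng.uniform(-1, 1, (1, 256, 3))
        mask = np.ones((1, 256), bool)
        out = net(imgs, pts, mask)
        (out.keypoints * out.keypoints).mean().backward()
        assert net.agg.beta.grad is not None and np.isfinite(net.agg.beta.grad).all()
        assert net.head1.alpha_raw.grad is not None
        assert net.head2.alpha_raw.grad is not None
        for p in net.parameters():
            assert p.grad is None or np.isfinite(p.grad).all()
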