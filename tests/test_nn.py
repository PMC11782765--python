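"""Gradient and contract checks for the numpy autodiff substrate."""

import numpy as np
import pytest

from occtkit import nn
from occtkit.nn import functional as F
from occtkit.nn.losses import LOSSES, get_loss
from occtkit.nn.optim import OPTIMIZERS, make_optimizer
from occtkit.nn.tensor import Tensor


def numeric_grad(fn, x, eps=1e-2):
    """Central-difference gradient of scalar fn w.r.t. array x (float32)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        g[i] = (fn(xp) - fn(xm)) / (2 * eps)
    return g


def check_grad(make_out, x, atol=2e-2):
    t = Tensor(x, requires_grad=True)
    out = make_out(t)
    out.sum().backward()
    num = numeric_grad(lambda a: float(make_out(Tensor(a)).sum().data), x)
    np.testing.assert_allclose(t.grad, num, atol=atol, rtol=2e-2)


class TestElementwise:
    @pytest.mark.parametrize("op", ["relu", "elu", "tanh", "sigmoid",
                                    "leaky_relu", "abs", "exp"])
    def test_unary_grads(self, rng, op):
        x = rng.normal(0, 1, (4, 5)).astype(np.float32)
        x += 0.05 * np.sign(x)  # keep away from kinks
        check_grad(lambda t: getattr(t, op)(), x)

    @pytest.mark.parametrize("name", ["softplus", "softsign", "gelu"])
    def test_composite_activations(self, rng, name):
        x = rng.normal(0, 1, (3, 4)).astype(np.float32)
        check_grad(F.ACTIVATIONS[name], x)

    def test_activation_values(self):
        x = Tensor(np.array([-1.0, 0.0, 2.0], dtype=np.float32))
        np.testing.assert_allclose(x.relu().data, [0, 0, 2])
        np.testing.assert_allclose(x.elu().data, [np.expm1(-1), 0, 2],
                                   rtol=1e-6)
        np.testing.assert_allclose(
            F.ACTIVATIONS["softsign"](x).data, [-0.5, 0, 2 / 3], rtol=1e-6)
        np.testing.assert_allclose(
            x.sigmoid().data, 1 / (1 + np.exp([1.0, 0.0, -2.0])), rtol=1e-6)

    def test_binary_grads(self, rng):
        x = rng.normal(0, 1, (3, 4)).astype(np.float32)
        y = rng.normal(0, 1, (3, 4)).astype(np.float32) + 3.0  # keep positive
        for fn in (lambda t: t * Tensor(y), lambda t: t / Tensor(y),
                   lambda t: t - Tensor(y), lambda t: t + Tensor(y)):
            check_grad(fn, x)

    def test_broadcast_grad(self, rng):
        x = rng.normal(0, 1, (4, 1, 5)).astype(np.float32)
        other = Tensor(rng.normal(0, 1, (4, 3, 5)).astype(np.float32))
        check_grad(lambda t: (t * other).sum(axis=(0, 2)), x)

    def test_fanout_accumulation(self, rng):
        # a node consumed twice must receive the sum of both contributions
        x = Tensor(np.ones(3, dtype=np.float32), requires_grad=True)
        out = x * 2.0 + x * 3.0
        out.sum().backward()
        np.testing.assert_allclose(x.grad, [5, 5, 5])


class TestMatmulReductions:
    def test_matmul_grad(self, rng):
        a = rng.normal(0, 1, (4, 3)).astype(np.float32)
        b = Tensor(rng.normal(0, 1, (3, 5)).astype(np.float32))
        check_grad(lambda t: t @ b, a)

    def test_batched_matmul_grad(self, rng):
        a = rng.normal(0, 1, (2, 3, 4)).astype(np.float32)
        b = Tensor(rng.normal(0, 1, (2, 4, 5)).astype(np.float32))
        check_grad(lambda t: t @ b, a)

    @pytest.mark.parametrize("axis,keepdims", [(None, False), (0, False),
                                               (1, True), ((0, 2), False)])
    def test_sum_mean_grad(self, rng, axis, keepdims):
        x = rng.normal(0, 1, (2, 3, 4)).astype(np.float32)
        check_grad(lambda t: t.sum(axis=axis, keepdims=keepdims) * 2.0, x)
        check_grad(lambda t: t.mean(axis=axis, keepdims=keepdims), x)

    def test_reshape_transpose_grad(self, rng):
        x = rng.normal(0, 1, (2, 3, 4)).astype(np.float32)
        check_grad(lambda t: t.reshape(6, 4).transpose(1, 0) * 1.5, x)


class TestConvPool:
    @pytest.mark.parametrize("stride,padding", [(1, 0), (1, 1), (2, 1),
                                                (1, "same")])
    def test_conv2d_grad(self, rng, stride, padding):
        x = rng.normal(0, 1, (2, 3, 6, 6)).astype(np.float32)
        w = Tensor(rng.normal(0, 0.5, (4, 3, 3, 3)).astype(np.float32),
                   requires_grad=True)
        b = Tensor(rng.normal(0, 0.5, 4).astype(np.float32),
                   requires_grad=True)
        check_grad(lambda t: F.conv2d(t, w, b, stride=stride,
                                      padding=padding), x)

    def test_conv2d_weight_grad(self, rng):
        x = Tensor(rng.normal(0, 1, (2, 3, 5, 5)).astype(np.float32))
        w0 = rng.normal(0, 0.5, (2, 3, 3, 3)).astype(np.float32)

        def by_weight(wt):
            return F.conv2d(x, wt, None, stride=1, padding=1)

        wt = Tensor(w0, requires_grad=True)
        by_weight(wt).sum().backward()
        num = numeric_grad(
            lambda a: float(by_weight(Tensor(a)).sum().data), w0)
        np.testing.assert_allclose(wt.grad, num, atol=2e-2, rtol=2e-2)

    def test_conv2d_matches_explicit_loops(self, rng):
        x = rng.normal(0, 1, (1, 2, 5, 5)).astype(np.float32)
        w = rng.normal(0, 1, (3, 2, 3, 3)).astype(np.float32)
        out = F.conv2d(Tensor(x), Tensor(w), None, stride=1, padding=0).data
        ref = np.zeros((1, 3, 3, 3))
        for co in range(3):
            for i in range(3):
                for j in range(3):
                    ref[0, co, i, j] = (x[0, :, i:i + 3, j:j + 3] *
                                        w[co]).sum()
        np.testing.assert_allclose(out, ref, rtol=1e-4, atol=1e-5)

    def test_conv_transpose_shape_and_grad(self, rng):
        x = rng.normal(0, 1, (2, 4, 3, 3)).astype(np.float32)
        w = Tensor(rng.normal(0, 0.5, (2, 4, 4, 4)).astype(np.float32))
        out = F.conv_transpose2d(Tensor(x), w, stride=2, padding=1)
        assert out.shape == (2, 2, 6, 6)  # doubles spatial size
        check_grad(lambda t: F.conv_transpose2d(t, w, stride=2, padding=1), x)

    @pytest.mark.parametrize("pool", [F.max_pool2d, F.avg_pool2d])
    def test_pool_grad(self, rng, pool):
        # all-distinct values with gaps > 2*eps so max-pool is locally smooth
        x = (rng.permutation(2 * 3 * 7 * 7) * 0.05).reshape(
            (2, 3, 7, 7)).astype(np.float32)
        check_grad(lambda t: pool(t, 3, 2, 1), x)

    def test_pool_shapes(self, rng):
        x = Tensor(rng.random((1, 1, 32, 32), dtype=np.float32))
        assert F.max_pool2d(x).shape == (1, 1, 16, 16)
        assert F.avg_pool2d(x).shape == (1, 1, 16, 16)

    def test_avg_pool_excludes_padding_from_divisor(self):
        x = Tensor(np.ones((1, 1, 4, 4), dtype=np.float32))
        out = F.avg_pool2d(x, 3, 2, 1)
        np.testing.assert_allclose(out.data, 1.0)  # corners average 4 ones


class TestLayers:
    def test_layernorm_grad_and_stats(self, rng):
        ln = nn.LayerNorm(6)
        x = rng.normal(2, 3, (4, 6)).astype(np.float32)
        check_grad(ln, x)
        out = ln(Tensor(x)).data
        np.testing.assert_allclose(out.mean(axis=-1), 0, atol=1e-5)
        np.testing.assert_allclose(out.std(axis=-1), 1, atol=1e-3)

    def test_batchnorm_train_eval(self, rng):
        bn = nn.BatchNorm2d(3)
        x = rng.normal(5, 2, (8, 3, 4, 4)).astype(np.float32)
        out = bn(Tensor(x)).data
        np.testing.assert_allclose(out.mean(axis=(0, 2, 3)), 0, atol=1e-4)
        bn.eval()
        out_eval = bn(Tensor(x)).data
        assert out_eval.shape == x.shape

    def test_attention_grad_and_shape(self, rng):
        attn = nn.MultiHeadSelfAttention(rng, 8, 2, dropout=0.0)
        x = rng.normal(0, 1, (2, 5, 8)).astype(np.float32)
        assert attn(Tensor(x)).shape == (2, 5, 8)
        check_grad(attn, x)

    def test_attention_rejects_bad_heads(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            nn.MultiHeadSelfAttention(rng, 8, 3)

    def test_dropout_eval_identity_train_scaling(self, rng):
        drop = nn.Dropout(rng, 0.5)
        x = Tensor(np.ones((1000,), dtype=np.float32))
        drop.eval()
        np.testing.assert_array_equal(drop(x).data, x.data)
        drop.train()
        out = drop(x).data
        assert set(np.unique(out)) <= {0.0, 2.0}
        assert abs(out.mean() - 1.0) < 0.15

    def test_state_dict_roundtrip(self, rng):
        d1 = nn.Dense(rng, 4, 3)
        d2 = nn.Dense(np.random.default_rng(99), 4, 3)
        d2.load_state_dict(d1.state_dict())
        x = rng.normal(0, 1, (2, 4)).astype(np.float32)
        np.testing.assert_array_equal(d1(Tensor(x)).data, d2(Tensor(x)).data)


class TestSoftmaxLossesOptim:
    def test_softmax_simplex_and_grad(self, rng):
        x = rng.normal(0, 3, (4, 6)).astype(np.float32)
        out = F.softmax(Tensor(x), axis=-1).data
        np.testing.assert_allclose(out.sum(axis=-1), 1, rtol=1e-5)
        mult = Tensor(rng.normal(0, 1, (4, 6)).astype(np.float32))
        check_grad(lambda t: F.softmax(t, axis=-1) * mult, x)

    def test_cce_matches_manual(self, rng):
        p = np.array([[0.7, 0.1, 0.1, 0.1], [0.25, 0.25, 0.25, 0.25]],
                     dtype=np.float32)
        onehot = np.eye(4, dtype=np.float32)[[0, 2]]
        loss = get_loss("categorical_crossentropy")(Tensor(p), onehot)
        expected = -(np.log(0.7) + np.log(0.25)) / 2
        assert abs(float(loss.data) - expected) < 1e-6

    def test_bce_matches_manual(self):
        p = np.array([[0.9], [0.2]], dtype=np.float32)
        t = np.array([[1.0], [0.0]], dtype=np.float32)
        loss = get_loss("binary_crossentropy")(Tensor(p), t)
        expected = -(np.log(0.9) + np.log(0.8)) / 2
        assert abs(float(loss.data) - expected) < 1e-6

    @pytest.mark.parametrize("name", sorted(LOSSES))
    def test_loss_grads(self, rng, name):
        logits = rng.normal(0, 1, (3, 4)).astype(np.float32)
        onehot = np.eye(4, dtype=np.float32)[[0, 1, 3]]
        check_grad(lambda t: LOSSES[name](F.softmax(t, axis=-1), onehot),
                   logits)

    @pytest.mark.parametrize("name", sorted(OPTIMIZERS))
    def test_optimizers_descend_quadratic(self, name):
        p = Tensor(np.array([5.0, -3.0], dtype=np.float32),
                   requires_grad=True)
        opt = make_optimizer(name, [p], lr=0.1)
        for _ in range(200):
            loss = (p * p).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert np.abs(p.data).max() < 0.5

    def test_unknown_names_rejected(self):
        with pytest.raises(ValueError, match="unknown optimizer"):
            make_optimizer("adagrad", [], lr=0.1)
        with pytest.raises(ValueError, match="unknown loss"):
            get_loss("hinge")
        with pytest.raises(ValueError, match="unknown activation"):
            nn.Activation("swish")
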