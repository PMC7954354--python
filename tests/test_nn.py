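"""The numpy autodiff engine: forward correctness against loop oracles and
gradient correctness against central finite differences (float64)."""

import numpy as np
import pytest

import oracles
from spinecodec import nn
from spinecodec.nn import functional as F


def numeric_grad(f, arr, eps=1e-6):
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        hi, lo = arr.copy(), arr.copy()
        hi[i] += eps
        lo[i] -= eps
        g[i] = (f(hi) - f(lo)) / (2 * eps)
    return g


@pytest.mark.parametrize("padding,dilation,groups,cin,cout", [
    ((0, 0), (1, 1), 1, 3, 2),
    ((1, 1), (1, 1), 1, 2, 3),
    ((0, 2), (1, 2), 1, 2, 2),   # asymmetric dilated 1x3-style geometry
    ((1, 1), (1, 1), 2, 4, 4),   # grouped
    ((1, 0), (1, 1), 4, 4, 4),   # depth-wise
])
def test_conv2d_matches_loop_oracle(rng, padding, dilation, groups, cin, cout):
    x = rng.standard_normal((2, cin, 6, 7))
    kh = 3 if padding[0] or dilation[0] > 1 else 2
    kw = 3 if padding[1] or dilation[1] > 1 else 2
    w = rng.standard_normal((cout, cin // groups, kh, kw))
    b = rng.standard_normal(cout)
    got = F.conv2d(nn.Tensor(x), nn.Tensor(w), nn.Tensor(b),
                   padding=padding, dilation=dilation, groups=groups).data
    want = oracles.conv2d_loop(x, w, b, padding, dilation, groups)
    np.testing.assert_allclose(got, want, atol=1e-10)


def test_conv2d_gradients_match_finite_differences(rng):
    x = rng.standard_normal((2, 4, 5, 6))
    w = rng.standard_normal((4, 2, 3, 3)) * 0.4
    b = rng.standard_normal(4) * 0.1
    kwargs = dict(padding=(1, 1), dilation=(1, 2), groups=2)

    def run(xd, wd, bd):
        out = F.conv2d(nn.Tensor(xd), nn.Tensor(wd), nn.Tensor(bd), **kwargs)
        return float((out.data ** 2).sum())

    xt = nn.Tensor(x, requires_grad=True)
    wt = nn.Tensor(w, requires_grad=True)
    bt = nn.Tensor(b, requires_grad=True)
    out = F.conv2d(xt, wt, bt, **kwargs)
    # sum-of-squares loss via the graph: use bce-free path, g = 2*out
    out.backward(2 * out.data)
    np.testing.assert_allclose(
        xt.grad, numeric_grad(lambda a: run(a, w, b), x), atol=1e-6)
    np.testing.assert_allclose(
        wt.grad, numeric_grad(lambda a: run(x, a, b), w), atol=1e-6)
    np.testing.assert_allclose(
        bt.grad, numeric_grad(lambda a: run(x, w, a), b), atol=1e-6)


@pytest.mark.parametrize("op_name", ["batch_norm_train", "batch_norm_eval",
                                     "max_pool", "upsample", "sigmoid_bce"])
def test_op_gradients_match_finite_differences(rng, op_name):
    x = rng.standard_normal((2, 3, 4, 4))
    gamma = rng.uniform(0.5, 1.5, 3)
    beta = rng.standard_normal(3) * 0.2
    target = (rng.random((2, 3, 4, 4)) > 0.5).astype(float)
    rm, rv = rng.standard_normal(3) * 0.1, rng.uniform(0.5, 2.0, 3)

    def build(xd, gd, bd):
        xt = nn.Tensor(xd, requires_grad=True)
        gt = nn.Tensor(gd, requires_grad=True)
        bt = nn.Tensor(bd, requires_grad=True)
        if op_name == "batch_norm_train":
            out = F.batch_norm2d(xt, gt, bt, True, rm.copy(), rv.copy())
        elif op_name == "batch_norm_eval":
            out = F.batch_norm2d(xt, gt, bt, False, rm.copy(), rv.copy())
        elif op_name == "max_pool":
            out = F.max_pool2x2(xt)
        elif op_name == "upsample":
            out = F.upsample_bilinear2x(xt)
        else:
            out = F.bce_loss(F.sigmoid(xt), target)
        if out.data.size > 1:
            loss = F.bce_loss(F.sigmoid(out),
                              np.zeros(out.shape))
        else:
            loss = out
        return xt, gt, bt, loss

    xt, gt, bt, loss = build(x, gamma, beta)
    loss.backward()

    def f(which, arr):
        args = {"x": x, "g": gamma, "b": beta}
        args[which] = arr
        return float(build(args["x"], args["g"], args["b"])[3].data)

    np.testing.assert_allclose(
        xt.grad, numeric_grad(lambda a: f("x", a), x), atol=2e-6)
    if op_name.startswith("batch_norm"):
        np.testing.assert_allclose(
            gt.grad, numeric_grad(lambda a: f("g", a), gamma), atol=2e-6)
        np.testing.assert_allclose(
            bt.grad, numeric_grad(lambda a: f("b", a), beta), atol=2e-6)


def test_max_pool_selects_block_maxima(rng):
    x = rng.standard_normal((1, 2, 6, 8))
    out = F.max_pool2x2(nn.Tensor(x)).data
    for i in range(3):
        for j in range(4):
            want = x[:, :, 2 * i:2 * i + 2, 2 * j:2 * j + 2].max(axis=(2, 3))
            np.testing.assert_array_equal(out[:, :, i, j], want)


def test_upsample_doubles_and_preserves_constants():
    x = np.full((1, 1, 5, 7), 3.25)
    out = F.upsample_bilinear2x(nn.Tensor(x)).data
    assert out.shape == (1, 1, 10, 14)
    np.testing.assert_allclose(out, 3.25)


def test_transposed_conv_restores_spatial_size(rng):
    layer = nn.ConvTranspose2x2(3, 5, rng=rng)
    out = layer(nn.Tensor(rng.standard_normal((1, 3, 7, 9))))
    assert out.shape == (1, 5, 8, 10)


def test_concat_splits_gradient(rng):
    a = nn.Tensor(rng.standard_normal((1, 2, 3, 3)), requires_grad=True)
    b = nn.Tensor(rng.standard_normal((1, 4, 3, 3)), requires_grad=True)
    out = F.concat([a, b])
    g = rng.standard_normal(out.shape)
    out.backward(g)
    np.testing.assert_array_equal(a.grad, g[:, :2])
    np.testing.assert_array_equal(b.grad, g[:, 2:])


def test_adam_converges_on_quadratic():
    p = nn.Parameter(np.array([5.0, -3.0], dtype=np.float64))
    opt = nn.Adam([p], lr=0.1, betas=(0.5, 0.999))
    for _ in range(500):
        p.grad = 2 * p.data
        opt.step()
    np.testing.assert_allclose(p.data, 0.0, atol=1e-4)


def test_forward_is_deterministic_in_eval_mode(rng):
    layer = nn.ConvBNReLU(2, 4, 3, padding=1, rng=rng)
    layer.eval()
    x = rng.standard_normal((1, 2, 8, 8)).astype(np.float32)
    a = layer(nn.Tensor(x)).data
    b = layer(nn.Tensor(x)).data
    assert np.array_equal(a, b)
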