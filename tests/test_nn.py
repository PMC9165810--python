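"""Layer engine: brute-force convolution oracles and gradient checks.

Internal tensors are time-major (T, maps, batch, channels).  Every
convolution variant is checked against explicit loops, and every layer's
backward pass against central finite differences of a random linear
functional of its output.
"""

import numpy as np
import pytest

from residual_eegnet import nn

RNG = np.random.default_rng(99)


def brute_temporal(x, w, pad_left):
    """Loop implementation of 'same' cross-correlation with map mixing."""
    T, Fi, N, C = x.shape
    Fo, _, k = w.shape
    xp = np.pad(x, ((pad_left, k - 1 - pad_left), (0, 0), (0, 0), (0, 0)))
    y = np.zeros((T, Fo, N, C))
    for t in range(T):
        for o in range(Fo):
            for i in range(Fi):
                for u in range(k):
                    y[t, o] += w[o, i, u] * xp[t + u, i]
    return y


def numeric_grad(f, x, indices, eps=1e-6):
    out = []
    for idx in indices:
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        out.append((f(xp) - f(xm)) / (2 * eps))
    return np.array(out)


@pytest.mark.parametrize("k", [3, 6, 16])
def test_temporal_conv_matches_brute_force(k):
    x = RNG.normal(size=(19, 3, 2, 4))
    conv = nn.TemporalConv(3, 5, k, RNG)
    np.testing.assert_allclose(conv.forward(x),
                               brute_temporal(x, conv.w.value, conv.pad_left),
                               atol=1e-10)


@pytest.mark.parametrize("k", [4, 7])
def test_depthwise_conv_matches_brute_force(k):
    x = RNG.normal(size=(17, 3, 2, 4))
    conv = nn.DepthwiseTemporalConv(3, k, RNG)
    w_mixed = np.zeros((3, 3, k))
    for f in range(3):
        w_mixed[f, f] = conv.w.value[f]
    np.testing.assert_allclose(conv.forward(x),
                               brute_temporal(x, w_mixed, conv.pad_left),
                               atol=1e-10)


@pytest.mark.parametrize("layer_factory", [
    lambda: nn.TemporalConv(3, 4, 6, RNG),
    lambda: nn.DepthwiseTemporalConv(3, 5, RNG),
    lambda: nn.PointwiseConv(3, 4, RNG),
    lambda: nn.SpatialConv(3, 4, 4, RNG),
    lambda: nn.ELU(),
    lambda: nn.AvgPoolTime(3),
    lambda: nn.Residual(nn.Sequential([nn.TemporalConv(3, 3, 4, RNG)])),
], ids=["temporal", "depthwise", "pointwise", "spatial", "elu", "avgpool",
        "residual"])
def test_backward_matches_finite_differences(layer_factory):
    layer = layer_factory()
    x = RNG.normal(size=(12, 3, 2, 4))
    y = layer.forward(x)
    probe = RNG.normal(size=y.shape)

    def scalar(xv):
        return float((layer.forward(xv) * probe).sum())

    layer.forward(x)
    for p in layer.parameters():
        p.zero_grad()
    gx = layer.backward(probe)
    idx = [(0, 0, 0, 0), (5, 1, 1, 2), (11, 2, 0, 3)]
    np.testing.assert_allclose(numeric_grad(scalar, x, idx),
                               [gx[i] for i in idx], rtol=1e-6, atol=1e-8)


def test_parameter_gradients_match_finite_differences():
    layer = nn.TemporalConv(2, 3, 5, RNG)
    x = RNG.normal(size=(11, 2, 2, 3))
    probe = RNG.normal(size=(11, 3, 2, 3))
    layer.forward(x)
    layer.w.zero_grad()
    layer.backward(probe)
    analytic = layer.w.grad.copy()
    for idx in [(0, 0, 0), (2, 1, 4), (1, 0, 2)]:
        w0 = layer.w.value.copy()
        eps = 1e-6
        layer.w.value[idx] += eps
        fp = float((layer.forward(x) * probe).sum())
        layer.w.value[...] = w0
        layer.w.value[idx] -= eps
        fm = float((layer.forward(x) * probe).sum())
        layer.w.value[...] = w0
        np.testing.assert_allclose((fp - fm) / (2 * eps), analytic[idx], rtol=1e-6)


class TestBatchNorm:
    def test_train_mode_standardizes_each_map(self):
        bn = nn.BatchNorm(3)
        x = RNG.normal(loc=2.0, scale=4.0, size=(10, 3, 4, 5))
        y = bn.forward(x, train=True)
        np.testing.assert_allclose(y.mean(axis=(0, 2, 3)), 0, atol=1e-10)
        np.testing.assert_allclose(y.std(axis=(0, 2, 3)), 1, atol=1e-3)

    def test_train_backward_matches_finite_differences(self):
        bn = nn.BatchNorm(2)
        x = RNG.normal(size=(6, 2, 3, 2))
        probe = RNG.normal(size=x.shape)
        bn.forward(x, train=True)
        bn.gamma.zero_grad(); bn.beta.zero_grad()
        gx = bn.backward(probe)

        def scalar(xv):
            fresh = nn.BatchNorm(2)
            fresh.gamma.value[...] = bn.gamma.value
            fresh.beta.value[...] = bn.beta.value
            return float((fresh.forward(xv, train=True) * probe).sum())

        idx = [(0, 0, 0, 0), (3, 1, 2, 1)]
        np.testing.assert_allclose(numeric_grad(scalar, x, idx),
                                   [gx[i] for i in idx], rtol=1e-5, atol=1e-8)

    def test_eval_mode_uses_running_stats_and_set_identity(self):
        bn = nn.BatchNorm(2)
        bn.set_identity()
        x = RNG.normal(size=(4, 2, 2, 2))
        np.testing.assert_allclose(bn.forward(x, train=False), x, atol=1e-12)


class TestPoolingAndDropout:
    def test_avgpool_floor_division_drops_remainder(self):
        pool = nn.AvgPoolTime(4)
        x = RNG.normal(size=(10, 1, 1, 1))
        y = pool.forward(x)
        assert y.shape[0] == 2
        np.testing.assert_allclose(y[0, 0, 0, 0], x[:4, 0, 0, 0].mean())
        g = pool.backward(np.ones_like(y))
        assert g.shape[0] == 10
        np.testing.assert_allclose(g[8:], 0)  # dropped tail gets zero gradient

    def test_dropout_eval_is_identity_train_preserves_scale(self):
        drop = nn.Dropout(0.25)
        x = np.ones((30, 4, 20, 10))
        np.testing.assert_array_equal(drop.forward(x, train=False), x)
        y = drop.forward(x, train=True, rng=np.random.default_rng(0))
        kept = y[y > 0]
        np.testing.assert_allclose(kept, 1 / 0.75)
        assert abs(y.mean() - 1.0) < 0.02


class TestMaxNorm:
    def test_projection_caps_norms(self):
        w = RNG.normal(size=(6, 4, 8))
        out = nn.project_maxnorm(w, 1.0)
        norms = np.linalg.norm(out.reshape(6, -1), axis=1)
        orig = np.linalg.norm(w.reshape(6, -1), axis=1)
        np.testing.assert_allclose(norms, np.minimum(orig, 1.0), atol=1e-6)

    def test_small_filters_untouched_large_halved(self):
        w = np.zeros((2, 1, 4))
        w[0, 0, 0] = 0.5
        w[1] = 1.0  # norm 2
        out = nn.project_maxnorm(w, 1.0)
        np.testing.assert_allclose(out[0], w[0])
        np.testing.assert_allclose(out[1], w[1] / 2)


def test_logsoftmax_normalizes_and_backward_checks():
    ls = nn.LogSoftmax()
    x = RNG.normal(size=(7, 3)) * 10
    y = ls.forward(x)
    np.testing.assert_allclose(np.exp(y).sum(axis=1), 1, atol=1e-12)
    probe = RNG.normal(size=y.shape)
    gx = ls.backward(probe)

    def scalar(xv):
        return float((nn.LogSoftmax().forward(xv) * probe).sum())

    idx = [(0, 0), (4, 2)]
    np.testing.assert_allclose(numeric_grad(scalar, x, idx),
                               [gx[i] for i in idx], rtol=1e-6)


def test_residual_identity_and_zero_cases():
    inner = nn.Sequential([nn.TemporalConv(2, 2, 3, RNG)])
    inner.layers[0].w.value[...] = 0.0
    res = nn.Residual(inner)
    x = RNG.normal(size=(9, 2, 2, 3))
    np.testing.assert_allclose(res.forward(x), x, atol=1e-12)
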