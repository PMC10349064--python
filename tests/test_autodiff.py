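"""Gradient correctness of the numpy NN core against finite differences."""

import numpy as np
import pytest

import pxafkit.autodiff as ad


def numeric_grad(build, arrays, which, seed_g, eps=1e-6):
    base = arrays[which]
    num = np.zeros_like(base)
    it = np.nditer(base, flags=["multi_index"])
    for _ in it:
        ix = it.multi_index
        acc = 0.0
        for sgn in (1.0, -1.0):
            shifted = [a.copy() for a in arrays]
            shifted[which][ix] += sgn * eps
            out = build(*[ad.Parameter(a) for a in shifted])
            acc += sgn * float((out.data * seed_g).sum())
        num[ix] = acc / (2 * eps)
    return num


CASES = [
    ("add", lambda a, b: a + b, [(3, 4), (3, 4)]),
    ("mul_broadcast", lambda a, b: a * b, [(3, 4), (1, 4)]),
    ("matmul", lambda a, b: a @ b, [(3, 4), (4, 2)]),
    ("mean_axes", lambda a: a.mean(axis=(2, 3)), [(2, 3, 4, 4)]),
    ("relu", ad.relu, [(5, 5)]),
    ("leaky_relu", lambda a: ad.leaky_relu(a, 0.2), [(5, 5)]),
    ("sigmoid", ad.sigmoid, [(6,)]),
    ("tanh", ad.tanh, [(6,)]),
    ("clip", lambda a: ad.clip(a, -0.5, 0.5), [(4, 4)]),
    ("concat", lambda a, b: ad.concat([a, b], axis=1), [(2, 3, 4), (2, 2, 4)]),
    ("conv1d_strided", lambda x, w, b: ad.conv1d(x, w, b, stride=2, padding=2),
     [(2, 3, 12), (4, 3, 5), (4,)]),
    ("conv1d_dilated", lambda x, w: ad.conv1d(x, w, padding=2, dilation=2),
     [(2, 3, 12), (4, 3, 3)]),
    ("conv1d_depthwise", lambda x, w: ad.conv1d(x, w, padding=1, groups=4),
     [(2, 4, 10), (4, 1, 3)]),
    ("conv2d_strided", lambda x, w, b: ad.conv2d(x, w, b, stride=2, padding=1),
     [(2, 3, 8, 8), (4, 3, 3, 3), (4,)]),
    ("conv2d_dilated", lambda x, w: ad.conv2d(x, w, padding=2, dilation=2),
     [(2, 3, 9, 9), (4, 3, 3, 3)]),
    ("conv2d_depthwise", lambda x, w: ad.conv2d(x, w, padding=1, groups=3),
     [(2, 3, 7, 7), (3, 1, 3, 3)]),
    ("max_pool", lambda x: ad.max_pool2d(x, 3, 2, 1), [(2, 3, 8, 8)]),
    ("avg_pool", lambda x: ad.avg_pool2d(x, 3, 1, 1), [(2, 3, 6, 6)]),
    ("upsample", lambda x: ad.upsample1d_nearest(x, 2), [(2, 3, 5)]),
    ("pad1d", lambda x: ad.pad1d(x, 2, 3), [(2, 3, 5)]),
    ("batch_norm", lambda x, g, b: ad.batch_norm(x, g, b, training=True),
     [(4, 3, 5), (3,), (3,)]),
    ("phase_shuffle",
     lambda x: ad.phase_shuffle1d(x, 2, np.random.default_rng(7)),
     [(2, 3, 10)]),
]


@pytest.mark.parametrize("name,build,shapes", CASES,
                         ids=[c[0] for c in CASES])
def test_gradients_match_finite_differences(name, build, shapes, rng):
    arrays = [rng.standard_normal(s) for s in shapes]
    tensors = [ad.Parameter(a.copy()) for a in arrays]
    out = build(*tensors)
    seed_g = rng.standard_normal(out.data.shape)
    out.backward(seed_g)
    for i, t in enumerate(tensors):
        num = numeric_grad(build, arrays, i, seed_g)
        scale = np.abs(num).max() + 1e-12
        assert np.abs(num - t.grad).max() / scale < 1e-6, f"{name} arg {i}"


def test_softmax_cross_entropy_gradient(rng):
    logits = ad.Parameter(rng.standard_normal((5, 2)))
    labels = np.array([0, 1, 1, 0, 1])
    ad.softmax_cross_entropy(logits, labels).backward()
    num = np.zeros_like(logits.data)
    for ix in np.ndindex(*logits.data.shape):
        for sgn in (1.0, -1.0):
            shifted = ad.Parameter(logits.data.copy())
            shifted.data[ix] += sgn * 1e-6
            num[ix] += sgn * ad.softmax_cross_entropy(shifted, labels).item()
        num[ix] /= 2e-6
    assert np.abs(num - logits.grad).max() < 1e-6


def test_bce_with_logits_gradient(rng):
    scores = ad.Parameter(rng.standard_normal(6))
    targets = np.array([0, 1, 0, 1, 1, 0], dtype=float)
    ad.bce_with_logits(scores, targets).backward()
    num = np.zeros_like(scores.data)
    for i in range(6):
        for sgn in (1.0, -1.0):
            shifted = ad.Parameter(scores.data.copy())
            shifted.data[i] += sgn * 1e-6
            num[i] += sgn * ad.bce_with_logits(shifted, targets).item()
        num[i] /= 2e-6
    assert np.abs(num - scores.grad).max() < 1e-6


def test_sgd_momentum_matches_manual_update():
    p = ad.Parameter(np.array([1.0, -2.0]))
    opt = ad.SGD([p], lr=0.1, momentum=0.9, weight_decay=0.0)
    p.grad = np.array([0.5, 0.5])
    opt.step()
    np.testing.assert_allclose(p.data, [0.95, -2.05])
    p.grad = np.array([0.5, 0.5])
    opt.step()  # buffer = 0.9*0.5 + 0.5 = 0.95
    np.testing.assert_allclose(p.data, [0.95 - 0.095, -2.05 - 0.095])


def test_batch_norm_eval_uses_running_stats(rng):
    x = ad.Tensor(rng.standard_normal((8, 3, 10)))
    gamma, beta = ad.Parameter(np.ones(3)), ad.Parameter(np.zeros(3))
    running = {}
    ad.batch_norm(x, gamma, beta, running, training=True, momentum=1.0)
    y = ad.batch_norm(x, gamma, beta, running, training=False)
    np.testing.assert_allclose(y.data.mean(axis=(0, 2)), 0.0, atol=1e-6)


def test_phase_shuffle_zero_is_identity(rng):
    x = ad.Tensor(rng.standard_normal((2, 3, 16)))
    y = ad.phase_shuffle1d(x, 0, np.random.default_rng(0))
    assert y is x


def test_phase_shuffle_preserves_length(rng):
    x = ad.Tensor(rng.standard_normal((2, 3, 16)))
    y = ad.phase_shuffle1d(x, 3, np.random.default_rng(1))
    assert y.shape == x.shape
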