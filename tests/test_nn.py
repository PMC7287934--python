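"""Gradient checks and optimizer behaviour for the autodiff engine."""

import numpy as np
import pytest

from retroseq.nn import (
    Adam,
    Tensor,
    concat,
    cross_entropy_logits,
    embedding,
    layer_norm,
    no_grad,
    stack,
)


def numerical_grad(f, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central-difference gradient of scalar f with respect to x."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        hi = f()
        x[i] = orig - eps
        lo = f()
        x[i] = orig
        g[i] = (hi - lo) / (2 * eps)
    return g


def check_grad(build, params, atol=2e-2):
    """Compare autodiff and numerical gradients for every parameter."""
    loss = build()
    loss.backward()
    for p in params:
        auto = p.grad.copy()
        p.grad = None
        num = numerical_grad(lambda: float(build().data), p.data)
        assert np.allclose(auto, num, atol=atol), (auto, num)


def test_grad_matmul_add_tanh():
    rng = np.random.default_rng(0)
    w = Tensor(rng.standard_normal((3, 4)) * 0.5, requires_grad=True)
    b = Tensor(np.zeros(4), requires_grad=True)
    x = Tensor(rng.standard_normal((5, 3)))

    def build():
        return ((x @ w + b).tanh() * (x @ w + b)).sum()

    check_grad(build, [w, b])


def test_grad_softmax_and_batched_matmul():
    rng = np.random.default_rng(1)
    q = Tensor(rng.standard_normal((2, 3, 4)) * 0.5, requires_grad=True)
    k = Tensor(rng.standard_normal((2, 3, 4)) * 0.5, requires_grad=True)

    def build():
        scores = q @ k.transpose(0, 2, 1)
        return (scores.softmax(axis=-1) @ k).sum()

    check_grad(build, [q, k])


def test_grad_layer_norm():
    rng = np.random.default_rng(2)
    x = Tensor(rng.standard_normal((4, 6)), requires_grad=True)
    g = Tensor(np.ones(6), requires_grad=True)
    b = Tensor(np.zeros(6), requires_grad=True)

    def build():
        return (layer_norm(x, g, b) * layer_norm(x, g, b)).sum()

    check_grad(build, [x, g, b])


def test_grad_cross_entropy_and_embedding():
    rng = np.random.default_rng(3)
    emb = Tensor(rng.standard_normal((7, 5)) * 0.5, requires_grad=True)
    w = Tensor(rng.standard_normal((5, 7)) * 0.5, requires_grad=True)
    idx = np.array([1, 3, 3, 6])
    targets = np.array([2, 0, 5, 1])
    weights = np.array([1.0, 1.0, 0.0, 1.0])  # one masked position

    def build():
        return cross_entropy_logits(embedding(emb, idx) @ w, targets, weights)

    check_grad(build, [emb, w])


def test_grad_concat_stack_chunk():
    rng = np.random.default_rng(4)
    a = Tensor(rng.standard_normal((3, 4)), requires_grad=True)
    b = Tensor(rng.standard_normal((3, 4)), requires_grad=True)

    def build():
        c = concat([a, b], axis=-1)
        parts = c.chunk(4, axis=-1)
        return (stack(parts, axis=0) * stack(parts, axis=0)).sum()

    check_grad(build, [a, b])


def test_broadcast_add_unbroadcasts_gradient():
    x = Tensor(np.ones((4, 3)), requires_grad=True)
    bias = Tensor(np.ones(3), requires_grad=True)
    (x + bias).sum().backward()
    assert bias.grad.shape == (3,)
    assert np.allclose(bias.grad, 4.0)
    assert np.allclose(x.grad, 1.0)


def test_no_grad_suppresses_tape():
    w = Tensor(np.ones((2, 2)), requires_grad=True)
    with no_grad():
        out = (w @ w).sum()
    assert not out.requires_grad
    out2 = (w @ w).sum()
    assert out2.requires_grad


def test_backward_requires_scalar():
    w = Tensor(np.ones((2, 2)), requires_grad=True)
    with pytest.raises(ValueError):
        (w @ w).backward()


def test_adam_reduces_quadratic():
    w = Tensor(np.array([5.0, -3.0]), requires_grad=True)
    opt = Adam({"w": w}, lr=0.1, grad_clip=0.0)
    for _ in range(300):
        loss = (w * w).sum()
        loss.backward()
        opt.step()
        opt.zero_grad()
    assert float((w.data ** 2).sum()) < 1e-3


def test_adam_warmup_schedule():
    w = Tensor(np.zeros(2), requires_grad=True)
    opt = Adam({"w": w}, lr=1.0, schedule="warmup", warmup_steps=10)
    rates = []
    for _ in range(20):
        (w * w).sum().backward()
        rates.append(opt.step())
        opt.zero_grad()
    assert rates[:10] == pytest.approx([0.1 * (i + 1) for i in range(10)])
    assert rates[10] == pytest.approx((10 / 11) ** 0.5)
    assert all(a >= b for a, b in zip(rates[10:], rates[11:]))
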