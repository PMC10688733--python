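"""Capsule primitives: squash closed forms, coupling, routing, margin loss."""

import numpy as np
import pytest

from capsoct.autodiff import Tensor
from capsoct.capsule_ops import (
    MarginLossParams,
    SquashSpec,
    capsule_lengths,
    coupling,
    margin_loss,
    predictions,
    route,
    squash_original,
    squash_power,
)


def norms(v):
    return np.linalg.norm(v, axis=-1)


class TestSquash:
    def test_zero_fixed_point(self):
        assert np.allclose(squash_original(np.zeros(4)), 0.0, atol=1e-6)
        assert np.allclose(squash_power(np.zeros(4), 3.0), 0.0, atol=1e-6)

    def test_unit_norm_halves(self):
        s = np.array([1.0, 0.0, 0.0])
        assert norms(squash_original(s)) == pytest.approx(0.5, abs=1e-6)

    def test_long_vector_closed_form(self):
        s = np.array([0.0, 10.0])
        v = squash_original(s)
        assert norms(v) == pytest.approx(100.0 / 101.0, abs=1e-6)
        assert np.allclose(v / norms(v), s / 10.0)  # direction preserved

    def test_power_n2_equals_original(self):
        s = np.random.default_rng(0).normal(size=(10, 6)) * 3
        assert np.allclose(squash_power(s, 2.0), squash_original(s), atol=1e-9)

    def test_power_n3_slower_initial_growth(self):
        s = np.array([0.5, 0.0])
        p = norms(squash_power(s, 3.0))
        assert p == pytest.approx(0.125 / 1.125, abs=1e-6)  # ~0.111
        assert p < norms(squash_original(s))  # original = 0.2

    @pytest.mark.parametrize("fn", [squash_original, lambda s: squash_power(s, 3.0)])
    def test_norm_below_one_monotone_and_direction(self, fn):
        mags = np.linspace(0.05, 20, 60)
        vecs = mags[:, None] * np.array([[0.6, 0.8]])
        out = fn(vecs)
        n = norms(out)
        assert np.all(n < 1.0)
        assert np.all(np.diff(n) > 0)  # monotone in input magnitude
        cos = (out * vecs).sum(-1) / (n * mags)
        assert np.allclose(cos, 1.0, atol=1e-9)

    def test_power_requires_positive_exponent(self):
        with pytest.raises(ValueError):
            squash_power(np.ones(3), 0.0)
        with pytest.raises(ValueError):
            SquashSpec("power", -1.0)


class TestCoupling:
    def test_zero_logits_softmax_uniform(self):
        c = coupling(np.zeros((3, 4)), "softmax")
        assert np.allclose(c, 0.25)

    def test_zero_logits_sigmoid_half(self):
        assert np.allclose(coupling(np.zeros((3, 4)), "sigmoid"), 0.5)

    def test_softmax_closed_form(self):
        c = coupling(np.array([[1.0, 2.0]]), "softmax")
        e = np.e
        assert np.allclose(c, [[e / (e + e**2), e**2 / (e + e**2)]])

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            coupling(np.zeros((2, 2)), "hardmax")


def manual_route(u_hat, r, mode, squash_fn):
    """Independent step-by-step routing oracle (explicit python loops)."""
    n_l, n_u, d = u_hat.shape
    b = np.zeros((n_l, n_u))
    for it in range(r):
        if mode == "softmax":
            c = np.exp(b) / np.exp(b).sum(axis=1, keepdims=True)
        else:
            c = 1.0 / (1.0 + np.exp(-b))
        v = np.zeros((n_u, d))
        for j in range(n_u):
            s = sum(c[i, j] * u_hat[i, j] for i in range(n_l))
            v[j] = squash_fn(s)
        for i in range(n_l):
            for j in range(n_u):
                b[i, j] += v[j] @ u_hat[i, j]
    return v, b


class TestRouting:
    def test_single_parent_softmax_is_plain_sum(self):
        u_hat = np.random.default_rng(1).normal(size=(5, 1, 4))
        v, state = route(u_hat, r=3, mode="softmax")
        assert np.allclose(state.couplings, 1.0)  # softmax over one parent
        assert np.allclose(v[0], squash_original(u_hat.sum(axis=0)[0]), atol=1e-9)

    def test_zero_predictions_stay_zero(self):
        v, state = route(np.zeros((4, 3, 2)), r=3, mode="softmax")
        assert np.allclose(v, 0.0, atol=1e-6)
        assert np.allclose(state.logits, 0.0, atol=1e-12)

    @pytest.mark.parametrize("mode", ["softmax", "sigmoid"])
    @pytest.mark.parametrize("r", [1, 2, 3])
    def test_matches_hand_unrolled_trace(self, mode, r):
        u_hat = np.random.default_rng(7).normal(size=(2, 2, 3))
        v, state = route(u_hat, r=r, mode=mode, squash=SquashSpec("original"))
        ev, eb = manual_route(
            u_hat, r, mode, lambda s: squash_original(s)
        )
        assert np.allclose(v, ev, atol=1e-6)

    def test_softmax_rows_normalised_every_iteration(self):
        u_hat = np.random.default_rng(3).normal(size=(6, 4, 5))
        _, state = route(u_hat, r=4, mode="softmax")
        assert len(state.coupling_history) == 4
        for c in state.coupling_history:
            assert np.allclose(c.sum(axis=-1), 1.0, atol=1e-6)

    def test_sigmoid_couplings_in_unit_interval(self):
        u_hat = np.random.default_rng(3).normal(size=(6, 4, 5))
        _, state = route(u_hat, r=3, mode="sigmoid")
        for c in state.coupling_history:
            assert np.all((c > 0) & (c < 1))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        u_hat = rng.normal(size=(7, 3, 4))
        perm = rng.permutation(7)
        v1, _ = route(u_hat, r=3, mode="softmax")
        v2, _ = route(u_hat[perm], r=3, mode="softmax")
        assert np.allclose(v1, v2, atol=1e-9)

    def test_one_iteration_closed_form(self):
        # r=1, b=0, softmax: uniform couplings 1/N_upper, then squash
        u_hat = np.random.default_rng(5).normal(size=(4, 3, 2))
        v, _ = route(u_hat, r=1, mode="softmax")
        expect = squash_original(u_hat.sum(axis=0) / 3)
        assert np.allclose(v, expect, atol=1e-9)

    def test_batched_matches_loop(self):
        u_hat = np.random.default_rng(2).normal(size=(3, 5, 2, 4))
        v, _ = route(u_hat, r=2, mode="sigmoid")
        for b in range(3):
            vb, _ = route(u_hat[b], r=2, mode="sigmoid")
            assert np.allclose(v[b], vb, atol=1e-9)

    def test_requires_iterations_and_shape(self):
        with pytest.raises(ValueError):
            route(np.zeros((2, 2, 2)), r=0)
        with pytest.raises(ValueError):
            route(np.zeros((4, 2)), r=1)

    def test_gradient_reaches_predictions(self):
        u_hat = Tensor(np.random.default_rng(0).normal(size=(3, 2, 4)), requires_grad=True)
        v, _ = route(u_hat, r=3, mode="sigmoid")
        (v * v).sum().backward()
        assert u_hat.grad is not None and np.any(u_hat.grad != 0)


class TestPredictions:
    def test_matches_per_capsule_matmul(self):
        rng = np.random.default_rng(4)
        u = rng.normal(size=(5, 3))
        W = rng.normal(size=(5, 2, 4, 3))
        u_hat = predictions(u, W)
        for i in range(5):
            for j in range(2):
                assert np.allclose(u_hat[i, j], W[i, j] @ u[i])


class TestMarginLoss:
    def test_true_class_at_upper_margin_zero(self):
        loss = margin_loss(np.array([0.9, 0.0]), np.array([1.0, 0.0]))
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_absent_class_at_lower_margin_zero(self):
        loss = margin_loss(np.array([0.9, 0.1]), np.array([1.0, 0.0]))
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        # m+=0.9, m-=0.1, lambda=0.5; norms (0.8, 0.3), first class true:
        # (0.9-0.8)^2 + 0.5*(0.3-0.1)^2 = 0.01 + 0.02 = 0.03
        loss = margin_loss(
            np.array([0.8, 0.3]),
            np.array([1.0, 0.0]),
            MarginLossParams(0.9, 0.1, 0.5),
        )
        assert loss == pytest.approx(0.03, abs=1e-12)

    def test_batch_mean(self):
        v = np.array([[0.8, 0.3], [0.9, 0.1]])
        T = np.array([[1.0, 0.0], [1.0, 0.0]])
        assert margin_loss(v, T) == pytest.approx(0.015, abs=1e-12)

    def test_rejects_non_one_hot(self):
        with pytest.raises(ValueError):
            margin_loss(np.array([0.5, 0.5]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            margin_loss(np.array([0.5, 0.5]), np.array([0.5, 0.5]))

    def test_params_validated(self):
        with pytest.raises(ValueError):
            MarginLossParams(m_plus=0.1, m_minus=0.9)


class TestCapsuleLengths:
    def test_scaled_unit_vector(self):
        v = 0.9 * np.array([[0.6, 0.8]])
        assert capsule_lengths(v)[0] == pytest.approx(0.9, abs=1e-6)

    def test_zero_capsule(self):
        assert capsule_lengths(np.zeros((1, 8)))[0] == pytest.approx(0.0, abs=1e-6)

    def test_matches_numpy_norms(self):
        v = np.random.default_rng(8).normal(size=(4, 16))
        assert np.allclose(capsule_lengths(v), np.linalg.norm(v, axis=-1), atol=1e-6)
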