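"""Unit and property tests for the sigmoid network core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from odormap.core_net import (
    GradState,
    NetParams,
    TrainConfig,
    backprop,
    forward,
    glorot_init,
    init_params,
    l1_penalty,
    load_params,
    lr_schedule,
    sample_loss,
    save_params,
    sgd_step,
    sigmoid,
    train_net,
)


def finite_difference_grads(params, x, target, lam, h=1e-6):
    """Central-difference gradient oracle over every coordinate."""

    def loss_at(p):
        y = forward(p, x)[-1]
        return sample_loss(y, target, p, lam)

    gw = [np.zeros_like(w) for w in params.weights]
    gb = [np.zeros_like(b) for b in params.biases]
    for l, w in enumerate(params.weights):
        for idx in np.ndindex(w.shape):
            p = params.copy()
            p.weights[l][idx] += h
            up = loss_at(p)
            p.weights[l][idx] -= 2 * h
            down = loss_at(p)
            gw[l][idx] = (up - down) / (2 * h)
    for l, b in enumerate(params.biases):
        for idx in np.ndindex(b.shape):
            p = params.copy()
            p.biases[l][idx] += h
            up = loss_at(p)
            p.biases[l][idx] -= 2 * h
            down = loss_at(p)
            gb[l][idx] = (up - down) / (2 * h)
    return gw, gb


def grad_relative_error(analytic, numeric):
    a = np.concatenate([g.ravel() for g in analytic[0] + analytic[1]])
    n = np.concatenate([g.ravel() for g in numeric[0] + numeric[1]])
    return np.linalg.norm(a - n) / max(np.linalg.norm(n), 1e-10)


class TestSigmoid:
    def test_zero_maps_to_half(self):
        assert sigmoid(np.array([0.0]))[0] == 0.5

    def test_antisymmetry(self, rng):
        a = rng.normal(scale=3, size=50)
        np.testing.assert_allclose(sigmoid(a) + sigmoid(-a), 1.0, atol=1e-12)

    def test_saturation_without_overflow(self):
        assert sigmoid(np.array([40.0]))[0] == pytest.approx(1.0, abs=1e-12)
        out = sigmoid(np.array([-1e4, 1e4]))
        assert np.all(np.isfinite(out))

    @given(st.floats(-1e6, 1e6, allow_nan=False))
    @settings(deadline=None, max_examples=50)
    def test_range_and_monotonicity(self, a):
        lo, hi = sigmoid(np.array([a, a + 1.0]))
        assert 0.0 <= lo <= hi <= 1.0


class TestForward:
    def test_zero_params_give_half_everywhere(self, rng):
        p = NetParams(
            [np.zeros((3, 2)), np.zeros((2, 3))], [np.zeros(3), np.zeros(2)]
        )
        acts = forward(p, rng.normal(size=2))
        for a in acts[1:]:
            np.testing.assert_array_equal(a, 0.5)

    def test_two_nested_logistics(self):
        p = NetParams([np.array([[1.0]]), np.array([[1.0]])], [np.zeros(1), np.zeros(1)])
        out = forward(p, np.array([0.0]))[-1]
        # sigmoid(0) = 0.5 then sigmoid(0.5)
        assert out[0] == pytest.approx(expit(0.5))

    def test_matches_hand_composed_chain(self, rng):
        p = init_params([2, 3, 2], 0.5, rng)
        x = rng.normal(size=2)
        h = expit(p.weights[0] @ x + p.biases[0])
        y = expit(p.weights[1] @ h + p.biases[1])
        np.testing.assert_array_equal(forward(p, x)[-1], y)

    def test_batch_rows_equal_vector_calls(self, rng):
        p = init_params([3, 4, 2], 0.3, rng)
        xs = rng.normal(size=(5, 3))
        batch = forward(p, xs)[-1]
        for i, x in enumerate(xs):
            np.testing.assert_array_equal(batch[i], forward(p, x)[-1])

    def test_shape_mismatch_names_layer(self, rng):
        p = init_params([3, 2], 0.1, rng)
        with pytest.raises(ValueError, match="layer 0"):
            forward(p, np.zeros(5))

    def test_activations_stay_in_unit_interval(self, rng):
        p = init_params([4, 3, 3, 2], 5.0, rng)
        acts = forward(p, rng.normal(scale=10, size=4))
        for a in acts[1:]:
            assert np.all((a > 0) & (a < 1))


class TestLoss:
    def test_perfect_output_zero_weights_is_zero(self):
        p = NetParams([np.zeros((2, 2))], [np.zeros(2)])
        assert sample_loss(np.array([0.3, 0.7]), np.array([0.3, 0.7]), p, 4e-7) == 0.0

    def test_squared_error_sum(self):
        p = NetParams([np.zeros((2, 2))], [np.zeros(2)])
        y, t = np.array([0.6, 0.3]), np.array([0.5, 0.5])
        assert sample_loss(y, t, p, 0.0) == pytest.approx(0.05)

    def test_l1_term_added_at_default_lambda(self):
        w = np.array([[1.0, -2.0], [0.5, 0.0]])
        p = NetParams([w], [np.zeros(2)])
        y, t = np.array([0.6, 0.3]), np.array([0.5, 0.5])
        assert sample_loss(y, t, p, 4e-7) == pytest.approx(0.05 + 4e-7 * 3.5)

    def test_length_mismatch_raises(self):
        p = NetParams([np.zeros((2, 2))], [np.zeros(2)])
        with pytest.raises(ValueError):
            sample_loss(np.zeros(2), np.zeros(3), p, 0.0)


class TestL1Penalty:
    def test_forced_arithmetic(self):
        p = NetParams([np.array([[1.0, -2.0, 3.0]])], [np.zeros(1)])
        assert l1_penalty(p, 0.1) == pytest.approx(0.6)

    def test_zero_weights_and_homogeneity(self, rng):
        p0 = NetParams([np.zeros((2, 3))], [np.zeros(2)])
        assert l1_penalty(p0, 0.5) == 0.0
        p = init_params([3, 2], 1.0, rng)
        assert l1_penalty(p, 0.2) == pytest.approx(2 * l1_penalty(p, 0.1))

    def test_biases_are_penalized(self):
        p = NetParams([np.zeros((1, 1))], [np.array([2.0])])
        assert l1_penalty(p, 0.5) == pytest.approx(1.0)


class TestBackprop:
    def test_stationary_at_zero_params_perfect_target(self):
        p = NetParams([np.zeros((2, 2)), np.zeros((2, 2))], [np.zeros(2), np.zeros(2)])
        # output is [0.5, 0.5]; with that as the target both terms vanish
        gw, gb = backprop(p, np.array([0.1, 0.2]), np.array([0.5, 0.5]), 0.0)
        for g in gw + gb:
            np.testing.assert_array_equal(g, 0.0)

    @pytest.mark.parametrize("sizes", [[2, 2, 2], [3, 4, 2], [5, 3, 4, 2]])
    def test_matches_finite_differences(self, sizes, rng):
        p = init_params(sizes, 0.8, rng)
        x = rng.normal(size=sizes[0])
        t = rng.uniform(size=sizes[-1])
        analytic = backprop(p, x, t, 0.0)
        numeric = finite_difference_grads(p, x, t, 0.0)
        assert grad_relative_error(analytic, numeric) < 1e-5

    def test_l1_term_is_additive_sign_of_weights(self, rng):
        p = init_params([2, 3, 2], 0.5, rng)
        x, t = rng.normal(size=2), rng.uniform(size=2)
        lam = 1e-3
        g0 = backprop(p, x, t, 0.0)
        g1 = backprop(p, x, t, lam)
        for l in range(2):
            np.testing.assert_allclose(
                g1[0][l], g0[0][l] + lam * np.sign(p.weights[l]), atol=1e-15
            )
            np.testing.assert_allclose(
                g1[1][l], g0[1][l] + lam * np.sign(p.biases[l]), atol=1e-15
            )


class TestSGDStep:
    def _one_weight(self, w=1.0):
        return NetParams([np.array([[w]])], [np.zeros(1)])

    def test_zero_gradient_no_momentum_is_identity(self):
        p = self._one_weight()
        state = GradState.zeros_like(p)
        cfg = TrainConfig(alpha=0.0)
        sgd_step(p, ([np.zeros((1, 1))], [np.zeros(1)]), state, cfg)
        assert p.weights[0][0, 0] == 1.0

    def test_single_weight_update(self):
        p = self._one_weight(1.0)
        state = GradState.zeros_like(p)
        cfg = TrainConfig(alpha=0.0)
        sgd_step(p, ([np.array([[0.5]])], [np.zeros(1)]), state, cfg)
        assert p.weights[0][0, 0] == pytest.approx(0.8)  # 1 - 0.4 * 0.5

    def test_momentum_uses_previous_realized_step(self):
        p = self._one_weight(1.0)
        state = GradState.zeros_like(p)
        cfg = TrainConfig(alpha=0.5, decay=1.0)
        g = ([np.array([[0.5]])], [np.zeros(1)])
        sgd_step(p, g, state, cfg)  # step -0.2 -> w=0.8
        sgd_step(p, g, state, cfg)  # step -0.2 + 0.5*(-0.2) = -0.3
        assert p.weights[0][0, 0] == pytest.approx(0.5)

    def test_noise_reproducible_and_unbiased(self):
        cfg = TrainConfig(alpha=0.0, noise_enabled=True)
        g = ([np.array([[0.5]])], [np.zeros(1)])

        def run(seed):
            p = self._one_weight(1.0)
            sgd_step(p, g, GradState.zeros_like(p), cfg, np.random.default_rng(seed))
            return p.weights[0][0, 0]

        assert run(3) == run(3)
        assert run(3) != run(4)
        draws = np.array([run(s) for s in range(10_000)])
        sd = cfg.noise_coeff * np.sqrt(2 * cfg.eta0)
        assert abs(draws.mean() - 0.8) < 3 * sd / np.sqrt(len(draws))

    def test_noise_requires_rng(self):
        p = self._one_weight()
        with pytest.raises(ValueError, match="rng"):
            sgd_step(
                p,
                ([np.zeros((1, 1))], [np.zeros(1)]),
                GradState.zeros_like(p),
                TrainConfig(noise_enabled=True),
            )


class TestSchedule:
    def test_reference_values(self):
        cfg = TrainConfig()
        assert lr_schedule(0, cfg) == pytest.approx(0.4)
        assert lr_schedule(1, cfg) == pytest.approx(0.396)

    def test_strictly_decreasing_and_positive(self):
        cfg = TrainConfig()
        etas = [lr_schedule(t, cfg) for t in range(500)]
        assert all(e > 0 for e in etas)
        assert all(a > b for a, b in zip(etas, etas[1:]))


class TestTrainNet:
    def test_loss_nonincreasing_without_noise(self, rng):
        """Plain gradient descent (no momentum, noise, decay) on a tiny set
        should not increase the per-epoch mean loss."""
        data = rng.uniform(0.2, 0.8, size=(5, 4))
        ok = 0
        for seed in range(10):
            cfg = TrainConfig(
                eta0=0.02, decay=1.0, lambda_l1=0.0, alpha=0.0, epochs=50, seed=seed
            )
            p = init_params([4, 3, 4], 0.03, np.random.default_rng(seed))
            log = train_net(p, data, data, cfg, np.random.default_rng(seed))
            if all(a >= b - 1e-12 for a, b in zip(log, log[1:])):
                ok += 1
        assert ok >= 9

    def test_deterministic_given_seed(self, rng):
        data = rng.uniform(size=(6, 3))
        cfg = TrainConfig(epochs=5)

        def run():
            p = init_params([3, 2, 3], 0.03, np.random.default_rng(0))
            train_net(p, data, data, cfg, np.random.default_rng(0))
            return p

        assert run() == run()

    def test_rejects_empty_or_mismatched(self):
        p = init_params([3, 2, 3], 0.03, np.random.default_rng(0))
        cfg = TrainConfig(epochs=1)
        with pytest.raises(ValueError):
            train_net(p, np.zeros((0, 3)), np.zeros((0, 3)), cfg, np.random.default_rng(0))
        with pytest.raises(ValueError):
            train_net(p, np.zeros((4, 3)), np.zeros((3, 3)), cfg, np.random.default_rng(0))


class TestParams:
    def test_shape_chain_validation(self):
        with pytest.raises(ValueError):
            NetParams([np.zeros((3, 2)), np.zeros((2, 4))], [np.zeros(3), np.zeros(2)])
        with pytest.raises(ValueError):
            NetParams([np.zeros((3, 2))], [np.zeros(4)])

    def test_serialization_round_trip(self, rng, tmp_path):
        p = init_params([4, 3, 2], 0.5, rng)
        path = tmp_path / "params.json"
        save_params(p, path)
        q = load_params(path)
        assert p == q and q.layer_sizes == [4, 3, 2]

    def test_glorot_scales_with_fan(self, rng):
        p = glorot_init([100, 4], rng)
        q = glorot_init([4, 4], rng)
        assert np.abs(p.weights[0]).max() < np.sqrt(6 / 104) + 1e-12
        assert np.abs(q.weights[0]).max() > np.abs(p.weights[0]).max()
        np.testing.assert_array_equal(p.biases[0], 0.0)
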