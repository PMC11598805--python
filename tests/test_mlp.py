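"""Activations, forward pass, backprop gradients, RPROP, and error reports."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metalret import mlp
from metalret.mlp import (
    ActivationSpec,
    ErrorReport,
    RpropConfig,
    RpropState,
    activation_eval,
    evaluate,
    forward,
    gradient,
    init_network,
    rprop_step,
    train,
    SELU_ALPHA,
    SELU_LAMBDA,
)


class TestActivations:
    def test_tanh_with_curvature(self):
        spec = ActivationSpec("tanh", curvature=0.7)
        value, deriv = activation_eval(spec, 0.0)
        assert value == 0.0
        assert deriv == pytest.approx(0.7)
        v1, _ = activation_eval(spec, 1.0)
        assert v1 == pytest.approx(math.tanh(0.7))

    def test_sigmoid_at_origin(self):
        value, deriv = activation_eval(ActivationSpec("sigmoid"), 0.0)
        assert value == pytest.approx(0.5)
        assert deriv == pytest.approx(0.25)

    def test_selu_negative_saturation(self):
        value, _ = activation_eval(ActivationSpec("selu"), -40.0)
        assert value == pytest.approx(-SELU_LAMBDA * SELU_ALPHA, rel=1e-6)

    def test_linear_gain(self):
        value, deriv = activation_eval(ActivationSpec("linear", gain=2.0), 3.0)
        assert value == pytest.approx(6.0)
        assert deriv == pytest.approx(2.0)

    @pytest.mark.parametrize("kind", ["sigmoid", "tanh", "relu", "threshold", "selu"])
    def test_all_kinds_map_zero_consistently(self, kind):
        value, _ = activation_eval(ActivationSpec(kind), 0.0)
        assert value == (0.5 if kind == "sigmoid" else 0.0)

    @pytest.mark.parametrize("kind", ["sigmoid", "tanh"])
    def test_bounded_kinds(self, kind, rng):
        values, _ = activation_eval(ActivationSpec(kind), rng.normal(0, 50, 100))
        assert np.all(np.abs(values) <= 1.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            ActivationSpec("swish")

    def test_finite_difference_derivatives(self, rng):
        h = 1e-6
        for kind in ("sigmoid", "tanh", "selu", "linear"):
            spec = ActivationSpec(kind, curvature=0.7)
            x = rng.normal(0, 2, 20)
            _, deriv = activation_eval(spec, x)
            fd = (activation_eval(spec, x + h)[0] - activation_eval(spec, x - h)[0]) / (2 * h)
            np.testing.assert_allclose(deriv, fd, rtol=1e-4, atol=1e-7)


class TestInit:
    def test_reproducible_for_equal_seeds(self):
        a, b = init_network(7, 5, seed=42), init_network(7, 5, seed=42)
        np.testing.assert_array_equal(a.w_hidden, b.w_hidden)
        np.testing.assert_array_equal(a.w_out, b.w_out)

    def test_shapes_and_range(self):
        model = init_network(7, 5, seed=0)
        assert model.w_hidden.shape == (5, 7)
        assert model.w_out.shape == (1, 5)
        assert np.all(np.abs(model.w_hidden) <= 0.5)
        assert np.all(model.b_hidden == 0) and np.all(model.b_out == 0)

    def test_nonpositive_sizes(self):
        with pytest.raises(ValueError):
            init_network(0, 5)


class TestForward:
    def test_zero_weights_return_output_bias(self):
        model = init_network(3, 4, seed=0)
        model.w_hidden[:] = 0
        model.w_out[:] = 0
        model.b_out[:] = 0.3
        assert forward(model, [9.0, -4.0, 2.0]) == pytest.approx(0.3)

    def test_hand_evaluated_1_1_1_net(self):
        model = mlp.MLPModel(
            w_hidden=[[1.0]], b_hidden=[0.0], w_out=[[1.0]], b_out=[0.0]
        )
        assert forward(model, [1.0]) == pytest.approx(math.tanh(0.7), abs=1e-9)

    def test_output_layer_linearity(self, rng):
        model = init_network(4, 3, seed=1)
        x = rng.normal(size=4)
        base = forward(model, x)
        model.w_out *= 2
        model.b_out *= 2
        assert forward(model, x) == pytest.approx(2 * base)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="inputs"):
            forward(init_network(4, 3, seed=0), [1.0, 2.0])

    def test_deterministic(self, rng):
        model = init_network(6, 5, seed=3)
        x = rng.normal(size=6)
        assert forward(model, x) == forward(model, x)


def _finite_difference(model, X, y, h=1e-6):
    grads = {}
    for name, arr in model.params().items():
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + h
            up, _ = gradient(model, X, y)
            arr[idx] = orig - h
            down, _ = gradient(model, X, y)
            arr[idx] = orig
            g[idx] = (up - down) / (2 * h)
        grads[name] = g
    return grads


class TestGradient:
    def test_perfect_predictions_zero_gradient(self):
        model = init_network(2, 3, seed=5)
        X = np.array([[0.1, -0.2], [0.4, 0.3]])
        y = np.array([forward(model, x) for x in X])
        loss, grads = gradient(model, X, y)
        assert loss == pytest.approx(0.0, abs=1e-24)
        for g in grads.values():
            np.testing.assert_allclose(g, 0.0, atol=1e-10)

    def test_matches_central_finite_differences(self, rng):
        model = init_network(3, 2, seed=7)
        X = rng.normal(size=(4, 3))
        y = rng.uniform(-1, 1, 4)
        _, grads = gradient(model, X, y)
        fd = _finite_difference(model, X, y)
        for name in grads:
            scale = max(np.abs(fd[name]).max(), 1e-3)
            np.testing.assert_allclose(
                grads[name], fd[name], rtol=1e-6, atol=1e-6 * scale
            )

    def test_duplicated_batch_leaves_gradient_unchanged(self, rng):
        model = init_network(3, 2, seed=9)
        X = rng.normal(size=(5, 3))
        y = rng.uniform(-1, 1, 5)
        _, g1 = gradient(model, X, y)
        _, g2 = gradient(model, np.vstack([X, X]), np.concatenate([y, y]))
        for name in g1:
            np.testing.assert_allclose(g1[name], g2[name], rtol=1e-12)

    def test_empty_batch(self):
        with pytest.raises(ValueError, match="empty"):
            gradient(init_network(2, 2, seed=0), np.empty((0, 2)), np.empty(0))


class TestRprop:
    def _state(self, shape=(1,), delta=0.5):
        params = {"w": np.zeros(shape)}
        cfg = RpropConfig(delta_init=delta)
        return params, RpropState.for_params(params, cfg), cfg

    def test_zero_gradient_changes_nothing(self):
        params, state, cfg = self._state()
        rprop_step(params, {"w": np.zeros(1)}, state, cfg)
        assert params["w"][0] == 0.0
        assert state.steps["w"][0] == 0.5

    def test_same_sign_growth_sequence(self):
        """Repeated positive gradients: steps 0.5, 0.6, 0.72, ... (×1.2)."""
        params, state, cfg = self._state()
        positions = []
        for _ in range(4):
            rprop_step(params, {"w": np.ones(1)}, state, cfg)
            positions.append(params["w"][0])
        steps = -np.diff([0.0] + positions)
        np.testing.assert_allclose(steps, [0.5, 0.6, 0.72, 0.864], rtol=1e-12)

    def test_sign_flip_halves_step_and_skips_once(self):
        params, state, cfg = self._state()
        rprop_step(params, {"w": np.ones(1)}, state, cfg)  # w: 0 → −0.5
        w_before = params["w"][0]
        rprop_step(params, {"w": -np.ones(1)}, state, cfg)  # flip: skip move
        assert params["w"][0] == w_before
        assert state.steps["w"][0] == pytest.approx(0.25)
        assert state.prev_grad["w"][0] == 0.0
        rprop_step(params, {"w": -np.ones(1)}, state, cfg)  # now moves +0.25
        assert params["w"][0] == pytest.approx(w_before + 0.25)

    def test_nan_gradient_raises(self):
        params, state, cfg = self._state()
        with pytest.raises(FloatingPointError, match="w"):
            rprop_step(params, {"w": np.array([np.nan])}, state, cfg)

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.sampled_from([-1.0, 0.0, 1.0]), min_size=1, max_size=60))
    def test_steps_always_clamped(self, signs):
        params, state, cfg = self._state(delta=0.5)
        for s in signs:
            rprop_step(params, {"w": np.array([s])}, state, cfg)
            assert cfg.delta_min <= state.steps["w"][0] <= cfg.delta_max

    def test_scalar_quadratic_oracle(self):
        """Minimising (w−3)² from w=0 reaches |w−3| < 1e−4 within 200 steps."""
        params = {"w": np.array([0.0])}
        cfg = RpropConfig()
        state = RpropState.for_params(params, cfg)
        for i in range(200):
            grad = {"w": 2 * (params["w"] - 3.0)}
            rprop_step(params, grad, state, cfg)
            if abs(params["w"][0] - 3.0) < 1e-4:
                break
        assert abs(params["w"][0] - 3.0) < 1e-4


class TestTrain:
    def test_sine_regression_converges(self):
        rng = np.random.default_rng(0)
        X = np.linspace(-1, 1, 50)[:, None]
        y = np.sin(np.pi * X[:, 0])
        model = init_network(1, 5, seed=0)
        trained, history = train(model, X, y, RpropConfig(epochs=2000))
        assert len(history) == 2000
        final = evaluate(trained, X, y).mean
        assert final < 0.01

    def test_best_weights_not_worse_than_history(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-1, 1, size=(30, 2))
        y = 0.3 * X[:, 0] - 0.5 * X[:, 1]
        trained, history = train(init_network(2, 5, seed=1), X, y,
                                 RpropConfig(epochs=500))
        assert evaluate(trained, X, y).mean <= history.min() + 1e-12

    def test_linear_hidden_equals_affine_least_squares(self, rng):
        """With linear activations throughout, the net can only represent an
        affine map; training should reach the least-squares residual computed
        independently."""
        from sklearn.linear_model import LinearRegression

        X = rng.uniform(-1, 1, size=(40, 3))
        y = 1.2 * X[:, 0] - 0.7 * X[:, 2] + 0.1
        model = init_network(
            3, 5, seed=2, hidden_activation=ActivationSpec("linear")
        )
        trained, _ = train(model, X, y, RpropConfig(epochs=2000))
        lsq_resid = np.mean(
            (LinearRegression().fit(X, y).predict(X) - y) ** 2
        )
        assert evaluate(trained, X, y).mean <= lsq_resid + 1e-6


class TestErrorReport:
    def test_direct_arithmetic(self):
        report = ErrorReport.from_residuals(np.array([0.1, 0.3]))
        np.testing.assert_allclose(report.per_example, [0.01, 0.09])
        assert report.mean == pytest.approx(0.05)
        assert report.min == pytest.approx(0.01)
        assert report.max == pytest.approx(0.09)

    def test_evaluate_zero_on_exact_predictions(self):
        model = init_network(2, 3, seed=4)
        X = np.array([[0.2, -0.1], [0.5, 0.5]])
        y = forward(model, X)
        report = evaluate(model, X, y)
        assert report.mean == 0.0 and report.max == 0.0

    def test_duplicating_dataset_keeps_mean(self, rng):
        model = init_network(2, 3, seed=4)
        X = rng.normal(size=(6, 2))
        y = rng.uniform(-1, 1, 6)
        a = evaluate(model, X, y)
        b = evaluate(model, np.vstack([X, X]), np.concatenate([y, y]))
        assert a.mean == pytest.approx(b.mean)
        assert a.n * 2 == b.n

    def test_mean_bounded_by_extremes(self, rng):
        report = ErrorReport.from_residuals(rng.normal(size=50))
        assert report.min <= report.mean <= report.max
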