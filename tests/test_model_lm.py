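"""Network forward pass, backprop Jacobian and Levenberg-Marquardt training."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from eegyaw.dataset import WindowedDataset
from eegyaw.model_lm import (
    MLPModel,
    TrainConfig,
    forward,
    init_model,
    jacobian,
    lm_step,
    load_model,
    save_model,
    train,
)


def random_model(rng, input_dim=6, hidden_dim=4, activation="tanh"):
    return MLPModel(
        W1=rng.normal(0, 0.5, (hidden_dim, input_dim)),
        b1=rng.normal(0, 0.5, hidden_dim),
        W2=rng.normal(0, 0.5, hidden_dim),
        b2=rng.normal(),
        hidden_activation=activation,
    )


def naive_forward(model, X):
    """Independent loop-based evaluation of the network."""
    out = []
    for row in X:
        h = []
        for k in range(model.hidden_dim):
            z = model.b1[k] + sum(
                model.W1[k, j] * row[j] for j in range(model.input_dim)
            )
            h.append(np.tanh(z) if model.hidden_activation == "tanh" else z)
        out.append(model.b2 + sum(model.W2[k] * h[k] for k in range(len(h))))
    return np.array(out)


class TestForward:
    def test_zero_network_predicts_zero(self):
        m = MLPModel(W1=np.zeros((4, 6)), b1=np.zeros(4), W2=np.zeros(4), b2=0.0)
        assert not forward(m, np.random.default_rng(0).normal(size=(5, 6))).any()

    def test_output_bias_passthrough(self, rng):
        m = random_model(rng)
        m.W2 = np.zeros_like(m.W2)
        m.b2 = 3.25
        np.testing.assert_allclose(forward(m, rng.normal(size=(7, 6))), 3.25)

    def test_matches_naive_symbolic_evaluation(self, rng):
        m = random_model(rng)
        X = rng.normal(size=(9, 6))
        np.testing.assert_allclose(forward(m, X), naive_forward(m, X), atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="features"):
            forward(random_model(rng), np.zeros((3, 5)))

    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            MLPModel(W1=np.full((2, 3), np.nan), b1=np.zeros(2), W2=np.zeros(2), b2=0.0)


class TestJacobian:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        m = random_model(rng)
        X = rng.normal(size=(5, 6))
        y = rng.normal(size=5)
        _, J = jacobian(m, X, y)
        theta = m.pack()
        h = 1e-6
        J_fd = np.empty_like(J)
        for k in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            J_fd[:, k] = (
                forward(m.with_params(tp), X) - forward(m.with_params(tm), X)
            ) / (2 * h)
        assert np.abs(J - J_fd).max() < 1e-6

    def test_linear_network_w2_columns_equal_hidden_outputs(self, rng):
        m = random_model(rng, activation="linear")
        X = rng.normal(size=(4, 6))
        _, J = jacobian(m, X, np.zeros(4))
        hidden = X @ m.W1.T + m.b1
        w2_cols = slice(m.hidden_dim * m.input_dim + m.hidden_dim,
                        m.hidden_dim * m.input_dim + 2 * m.hidden_dim)
        np.testing.assert_allclose(J[:, w2_cols], hidden, atol=1e-14)

    def test_duplicated_examples_duplicate_rows(self, rng):
        m = random_model(rng)
        X = rng.normal(size=(3, 6))
        X2 = np.vstack([X, X[1:2]])
        _, J = jacobian(m, X2, np.zeros(4))
        np.testing.assert_array_equal(J[3], J[1])

    def test_residual_sign_convention(self, rng):
        """e = y - yhat, J = d yhat / d theta."""
        m = random_model(rng)
        X = rng.normal(size=(4, 6))
        y = rng.normal(size=4)
        e, _ = jacobian(m, X, y)
        np.testing.assert_allclose(e, y - forward(m, X), atol=1e-14)


class TestLMStep:
    def test_solves_linear_least_squares_in_one_step(self, rng):
        """From a zero-response linear start, one nearly undamped step lands
        on the ordinary-least-squares solution."""
        X = rng.normal(size=(50, 3))
        beta = np.array([1.5, -2.0, 0.5])
        y = X @ beta + 0.7
        m = MLPModel(
            W1=np.zeros((1, 3)), b1=np.zeros(1), W2=np.ones(1), b2=0.0,
            hidden_activation="linear",
        )
        candidate, _ = lm_step(m, X, y, mu=1e-9)
        A = np.column_stack([X, np.ones(50)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        expect = A @ coef
        np.testing.assert_allclose(forward(candidate, X), expect, atol=1e-8)

    def test_large_damping_approaches_scaled_gradient(self, rng):
        m = random_model(rng)
        X = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        mu = 1e9
        candidate, _ = lm_step(m, X, y, mu=mu)
        delta = candidate.pack() - m.pack()
        e, J = jacobian(m, X, y)
        grad_step = J.T @ e / mu
        assert np.linalg.norm(delta - grad_step) / np.linalg.norm(delta) < 1e-3

    def test_zero_residual_gives_zero_step(self, rng):
        m = random_model(rng)
        X = rng.normal(size=(20, 6))
        y = forward(m, X)
        candidate, predicted = lm_step(m, X, y, mu=1e-3)
        np.testing.assert_allclose(candidate.pack(), m.pack(), atol=1e-10)
        assert predicted < 1e-18


def planted_dataset(rng, n=300, input_dim=5, noise=0.0):
    teacher = random_model(rng, input_dim=input_dim, hidden_dim=3)
    X = rng.normal(size=(n, input_dim))
    y = forward(teacher, X) + noise * rng.normal(size=n)
    return WindowedDataset(X=X, y=y, index_map=np.arange(n))


class TestTrain:
    @pytest.mark.parametrize("seed", range(20))
    def test_accepted_sse_trajectory_monotone(self, seed):
        rng = np.random.default_rng(seed)
        ds = planted_dataset(rng, noise=0.1)
        _, report = train(ds, TrainConfig(hidden_dim=4, max_epochs=25), seed=seed)
        assert all(b <= a + 1e-12 for a, b in
                   zip(report.sse_trajectory, report.sse_trajectory[1:]))

    def test_same_seed_reproduces_trajectory_exactly(self, rng):
        ds = planted_dataset(rng, noise=0.05)
        cfg = TrainConfig(hidden_dim=4, max_epochs=15)
        _, r1 = train(ds, cfg, seed=3)
        _, r2 = train(ds, cfg, seed=3)
        assert r1.sse_trajectory == r2.sse_trajectory
        assert r1.final_mu == r2.final_mu

    def test_constant_target_fitted_to_machine_precision(self, rng):
        X = rng.normal(size=(100, 4))
        ds = WindowedDataset(X=X, y=np.full(100, 0.7), index_map=np.arange(100))
        model, report = train(ds, TrainConfig(hidden_dim=3, max_epochs=50), seed=0)
        assert report.sse_trajectory[-1] < 1e-10
        np.testing.assert_allclose(forward(model, X), 0.7, atol=1e-5)

    def test_recovers_planted_function(self, rng):
        ds = planted_dataset(rng, n=400)
        model, report = train(ds, TrainConfig(hidden_dim=6, max_epochs=120), seed=1)
        resid = ds.y - forward(model, ds.X)
        assert np.mean(resid**2) < 1e-4 * np.var(ds.y)

    def test_agrees_with_scipy_lm_on_small_problem(self, rng):
        """Independent optimizer route: scipy's LM reaches the same SSE floor."""
        ds = planted_dataset(rng, n=200, input_dim=4)
        cfg = TrainConfig(hidden_dim=3, max_epochs=200)
        model, report = train(ds, cfg, seed=2)
        m0 = init_model(4, 3, seed=2)

        def resid(theta):
            return ds.y - forward(m0.with_params(theta), ds.X)

        def jac(theta):
            _, J = jacobian(m0.with_params(theta), ds.X, ds.y)
            return -J

        sol = least_squares(resid, m0.pack(), jac=jac, method="lm", max_nfev=2000)
        ours = report.sse_trajectory[-1]
        theirs = 2 * sol.cost
        assert ours <= theirs * 1.5 + 1e-8

    def test_empty_training_set_rejected(self):
        ds = WindowedDataset(X=np.zeros((0, 3)), y=np.zeros(0), index_map=np.zeros(0))
        with pytest.raises(ValueError, match="empty"):
            train(ds)

    def test_stop_reason_reported(self, rng):
        ds = planted_dataset(rng, noise=0.2)
        _, report = train(ds, TrainConfig(hidden_dim=4, max_epochs=5), seed=0)
        assert report.stop_reason in {"max_epochs", "gradient_tol", "mu_overflow", "sse_tol"}
        assert report.epochs_run <= 5


class TestSerialization:
    def test_round_trip_preserves_predictions(self, rng, tmp_path):
        m = random_model(rng)
        X = rng.normal(size=(10, 6))
        path = tmp_path / "model.json"
        save_model(m, path)
        m2 = load_model(path)
        np.testing.assert_array_equal(forward(m, X), forward(m2, X))
        assert m2.hidden_activation == m.hidden_activation
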