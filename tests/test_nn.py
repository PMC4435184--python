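import dataclasses

import numpy as np
import pytest

from palpinv import nn
from palpinv.fem import FeatureTriple

from conftest import smooth_inverse_dataset


def _identity_scaled(w):
    w = dataclasses.replace(
        w,
        input_scaler=nn.AffineScaler.identity(w.sizes[0]),
        output_scaler=nn.AffineScaler.identity(w.sizes[-1]),
    )
    w.input_scaler.fitted = w.output_scaler.fitted = True
    return w


def _random_dataset(n, seed, dim=3):
    rng = np.random.default_rng(seed)
    return nn.Dataset(X=rng.uniform(0, 1, (n, dim)), Y=rng.uniform(0, 1, (n, 3)), ids=np.arange(n))


class TestInit:
    def test_seeded_determinism_and_sensitivity(self):
        a, b, c = nn.init_network(0), nn.init_network(0), nn.init_network(1)
        assert all(np.array_equal(x, y) for x, y in zip(a.weights, b.weights))
        assert any(not np.array_equal(x, y) for x, y in zip(a.weights, c.weights))

    def test_weight_scale_bound(self):
        w = nn.init_network(5)
        for W in w.weights:
            assert np.all(np.abs(W) <= 1.0)
        for b in w.biases:
            assert np.all(b == 0)


class TestForwardPass:
    def test_zero_network_outputs_final_bias(self):
        w = nn.init_network(0)
        zero = w.from_vector(np.zeros(w.n_params))
        zero = _identity_scaled(zero)
        out = nn.forward_pass(zero, np.array([3.0, -1.0, 7.0]))
        assert np.allclose(out, 0.0)

    def test_hidden_activations_bounded(self):
        w = _identity_scaled(nn.init_network(3))
        # +-30 is far into the sigmoid tails but below float saturation
        A = nn._forward_scaled(w, np.array([[30.0, -30.0, 0.0]]))
        for a in A[1:-1]:
            assert np.all((a > 0) & (a < 1))

    def test_matches_independent_loop_implementation(self):
        # plain per-record loop oracle, independent of the vectorized path
        def loop_forward(w, x):
            a = (np.asarray(x) - w.input_scaler.lo) / (w.input_scaler.hi - w.input_scaler.lo)
            for name, W, b in zip(w.activations, w.weights, w.biases):
                z = W @ a + b
                a = 1 / (1 + np.exp(-z)) if name == "sigmoid" else z
            return a * (w.output_scaler.hi - w.output_scaler.lo) + w.output_scaler.lo

        rng = np.random.default_rng(0)
        for seed in range(10):
            w = _identity_scaled(nn.init_network(seed))
            x = rng.normal(size=3)
            assert np.allclose(nn.forward_pass(w, x), loop_forward(w, x), rtol=1e-12)

    def test_feature_triple_input(self):
        w = _identity_scaled(nn.init_network(1))
        ft = FeatureTriple(0.1, 2.0, 60.0)
        assert np.allclose(nn.forward_pass(w, ft), nn.forward_pass(w, ft.as_array()))


class TestJacobian:
    @pytest.mark.parametrize("seed", range(20))
    def test_backprop_matches_central_differences(self, seed):
        w = _identity_scaled(nn.init_network(seed))
        data = _random_dataset(6, seed + 100)
        x0 = w.to_vector()
        e, J = nn.error_and_jacobian(w, data, x0)
        h = 1e-6
        Jfd = np.empty_like(J)
        for j in range(len(x0)):
            xp, xm = x0.copy(), x0.copy()
            xp[j] += h
            xm[j] -= h
            Jfd[:, j] = (nn.residuals(w, data, xp) - nn.residuals(w, data, xm)) / (2 * h)
        assert np.abs(J - Jfd).max() <= 1e-6 * max(np.abs(Jfd).max(), 1.0)

    def test_gradient_consistent_with_energy(self):
        w = _identity_scaled(nn.init_network(2))
        data = _random_dataset(8, 3)
        x0 = w.to_vector()
        e, J = nn.error_and_jacobian(w, data, x0)
        g = 2 * J.T @ e
        h = 1e-6
        for j in range(0, len(x0), 7):
            xp, xm = x0.copy(), x0.copy()
            xp[j] += h
            xm[j] -= h
            ep = nn.residuals(w, data, xp)
            em = nn.residuals(w, data, xm)
            gfd = (ep @ ep - em @ em) / (2 * h)
            assert abs(g[j] - gfd) <= 1e-5 * max(abs(gfd), 1.0)

    def test_duplicated_records_duplicate_rows(self):
        w = _identity_scaled(nn.init_network(4))
        data = _random_dataset(5, 9)
        dup = nn.Dataset(
            X=np.vstack([data.X, data.X]), Y=np.vstack([data.Y, data.Y]), ids=np.arange(10)
        )
        e1, J1 = nn.error_and_jacobian(w, data)
        e2, J2 = nn.error_and_jacobian(w, dup)
        assert len(e2) == 2 * len(e1)
        assert np.array_equal(e2, np.concatenate([e1, e1]))
        assert np.array_equal(J2, np.vstack([J1, J1]))


class TestLMA:
    def test_one_accepted_step_solves_linear_least_squares(self):
        # single linear layer => residual linear in parameters => Gauss-Newton
        # (mu -> 0) lands on the OLS solution in one accepted step
        rng = np.random.default_rng(0)
        w = _identity_scaled(nn.init_network(3, sizes=(3, 3), activations=("linear",)))
        X = rng.uniform(0, 1, (20, 3))
        Y = X @ rng.normal(size=(3, 3)).T + 0.3
        data = nn.Dataset(X=X, Y=Y, ids=np.arange(20))
        cfg = nn.TrainConfig(algorithm="LMA", max_iter=1, mu0=1e-10)
        wt, hist = nn.train_lma(w, data, cfg)
        e = nn.residuals(wt, data)
        # OLS residual for the augmented design (X with intercept)
        A = np.column_stack([X, np.ones(20)])
        resid = Y - A @ np.linalg.lstsq(A, Y, rcond=None)[0]
        assert len(hist) == 2
        assert float(e @ e) <= (resid**2).sum() + 1e-8

    def test_large_mu_step_is_steepest_descent(self):
        w = _identity_scaled(nn.init_network(1))
        data = _random_dataset(10, 2)
        e, J = nn.error_and_jacobian(w, data)
        g = J.T @ e
        H = J.T @ J
        mu = 1e12
        dx = np.linalg.solve(H + mu * np.eye(len(g)), g)
        cos = (dx @ g) / (np.linalg.norm(dx) * np.linalg.norm(g))
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 1.0

    def test_mu_sweep_rotates_monotonically_to_gauss_newton(self):
        # direction angle to the gradient grows monotonically as mu decreases
        w = _identity_scaled(nn.init_network(6))
        data = _random_dataset(12, 5)
        e, J = nn.error_and_jacobian(w, data)
        g = J.T @ e
        H = J.T @ J
        angles = []
        for mu in np.logspace(8, -8, 30):
            dx = np.linalg.solve(H + mu * np.eye(len(g)), g)
            cos = (dx @ g) / (np.linalg.norm(dx) * np.linalg.norm(g))
            angles.append(np.degrees(np.arccos(np.clip(cos, -1, 1))))
        assert all(b >= a - 1e-9 for a, b in zip(angles, angles[1:]))

    def test_accepted_history_nonincreasing(self):
        for seed in range(5):
            data = smooth_inverse_dataset(25, seed)
            w = nn.init_network(seed)
            wt, hist = nn.train_lma(w, data, nn.TrainConfig(algorithm="LMA", max_iter=30))
            assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))


class TestSCGA:
    def test_finite_termination_on_quadratic(self):
        # conjugate-gradient finite termination: 5-variable SPD quadratic
        # reaches the minimum to 1e-8 within ~5 iterations
        A = np.array(
            [
                [4.0, 1, 0, 0, 0],
                [1, 3, 0.5, 0, 0],
                [0, 0.5, 2, 0.3, 0],
                [0, 0, 0.3, 5, 1],
                [0, 0, 0, 1, 2.5],
            ]
        )
        b = np.array([1.0, 2, -1, 0.5, 3])
        xstar = np.linalg.solve(A, b)
        Estar = 0.5 * xstar @ A @ xstar - b @ xstar
        x, hist = nn.scg_minimize(
            lambda x: 0.5 * x @ A @ x - b @ x, lambda x: A @ x - b, np.zeros(5), max_iter=6
        )
        assert hist[5] - Estar < 1e-8

    def test_accepted_steps_never_increase_error(self):
        for seed in range(5):
            data = smooth_inverse_dataset(25, seed + 50)
            wt, hist = nn.train_scga(
                nn.init_network(seed), data, nn.TrainConfig(algorithm="SCGA", max_iter=60)
            )
            assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))

    def test_no_hessian_materialized(self):
        # the closure only ever receives vectors; guard by intercepting numpy
        # allocations of size N x N through the gradient calls
        calls = []

        def f(x):
            return float(x @ x)

        def g(x):
            calls.append(x.shape)
            return 2 * x

        n = 200
        x, hist = nn.scg_minimize(f, g, np.ones(n), max_iter=10)
        assert all(shape == (n,) for shape in calls)
        assert hist[-1] < hist[0]

    def test_seeded_training_bit_reproducible(self):
        data = smooth_inverse_dataset(20, 11)
        cfg = nn.TrainConfig(algorithm="SCGA", max_iter=25)
        w1, h1 = nn.train_scga(nn.init_network(3), data, cfg)
        w2, h2 = nn.train_scga(nn.init_network(3), data, cfg)
        assert h1 == h2
        assert np.array_equal(w1.to_vector(), w2.to_vector())


class TestTrainersReduceError:
    @pytest.mark.parametrize("algo", ["LMA", "SCGA"])
    def test_final_error_below_initial(self, algo, smooth_dataset):
        for seed in range(10):
            cfg = nn.TrainConfig(algorithm=algo, max_iter=40)
            w = nn.init_network(seed)
            _, hist = nn.train(w, smooth_dataset, cfg)
            assert hist[-1] < hist[0]


class TestScalers:
    def test_minmax_definition_and_round_trip(self, smooth_dataset):
        xin, xout = nn.fit_scalers(smooth_dataset)
        Xs = xin.scale(smooth_dataset.X)
        assert np.allclose(Xs.min(axis=0), 0) and np.allclose(Xs.max(axis=0), 1)
        x = smooth_dataset.X[3]
        assert np.allclose(xin.unscale(xin.scale(x)), x, atol=1e-12)

    def test_zero_range_channel_rejected(self):
        data = nn.Dataset(X=np.ones((5, 3)), Y=np.random.default_rng(0).uniform(size=(5, 3)), ids=np.arange(5))
        with pytest.raises(ValueError, match="zero-range"):
            nn.fit_scalers(data)

    def test_test_values_may_leave_unit_interval(self, smooth_dataset):
        # scalers fitted on a training split only: held-out extremes land
        # outside [0, 1] by design (no leakage of test statistics)
        order = np.argsort(smooth_dataset.X[:, 0])
        train = smooth_dataset.subset(order[:-5])
        test = smooth_dataset.subset(order[-5:])
        xin, _ = nn.fit_scalers(train)
        assert np.any(xin.scale(test.X) > 1)


class TestPredict:
    def test_training_fit_recovers_training_points(self, smooth_dataset):
        cfg = nn.TrainConfig(algorithm="LMA", max_iter=200)
        w = nn.init_network(0)
        w, hist = nn.train(w, smooth_dataset, cfg)
        pred = nn.forward_pass(w, smooth_dataset.X)
        rel = np.abs((pred - smooth_dataset.Y) / smooth_dataset.Y)
        assert np.median(rel) < 0.05

    def test_unfitted_scalers_flagged(self):
        w = nn.init_network(0)
        with pytest.raises(ValueError, match="scalers"):
            nn.predict_parameters(w, FeatureTriple(0.1, 1.0, 10.0))

    def test_deterministic(self, smooth_dataset):
        w = nn.init_network(0)
        xin, xout = nn.fit_scalers(smooth_dataset)
        w = dataclasses.replace(w, input_scaler=xin, output_scaler=xout)
        ft = FeatureTriple(0.05, 1.5, 50.0)
        assert np.array_equal(nn.predict_parameters(w, ft), nn.predict_parameters(w, ft))


def test_network_serialization_round_trip(tmp_path, smooth_dataset):
    w = nn.init_network(9)
    xin, xout = nn.fit_scalers(smooth_dataset)
    w = dataclasses.replace(w, input_scaler=xin, output_scaler=xout)
    path = tmp_path / "net.txt"
    nn.save_network(w, path)
    back = nn.load_network(path)
    assert back.sizes == w.sizes and back.activations == w.activations
    assert np.array_equal(back.to_vector(), w.to_vector())
    assert np.array_equal(back.input_scaler.lo, w.input_scaler.lo)
    x = np.array([1.0, 2.0, 3.0])
    assert np.array_equal(nn.forward_pass(back, x), nn.forward_pass(w, x))
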