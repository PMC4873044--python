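import numpy as np
import pytest

from smoothpls.kalman import (KalmanParams, extend_with_derivatives,
                              kf_filter, kf_fit)

from _oracles import kalman_reference


def _simulate(rng, A, H, W, Q, N, y0=None):
    m, n = A.shape[0], H.shape[0]
    y = np.zeros(m) if y0 is None else y0
    Ys, Xs = np.empty((N, m)), np.empty((N, n))
    cW = np.linalg.cholesky(W + 1e-15 * np.eye(m))
    cQ = np.linalg.cholesky(Q + 1e-15 * np.eye(n))
    for k in range(N):
        y = A @ y + cW @ rng.standard_normal(m)
        Ys[k] = y
        Xs[k] = H @ y + cQ @ rng.standard_normal(n)
    return Xs, Ys


class TestExtendWithDerivatives:
    def test_linear_trajectory_gives_constant_velocity(self):
        t = np.arange(10.0) * 0.1
        Y = np.stack([2 * t, -t, 0.5 * t], axis=1)
        ext = extend_with_derivatives(Y, 0.1)
        assert ext.shape == (10, 9)
        assert np.allclose(ext[1:, 3:6], [2, -1, 0.5])
        assert np.allclose(ext[2:, 6:9], 0.0, atol=1e-10)

    def test_quadratic_trajectory_derivative_chain(self):
        t = np.arange(20.0) * 0.1
        Y = np.stack([t**2, t**2, t**2], axis=1)
        ext = extend_with_derivatives(Y, 0.1)
        # velocity linear in t, acceleration constant 2 on interior rows
        vel = ext[:, 3]
        assert np.allclose(np.diff(vel[1:]), 0.02 / 0.1, atol=1e-10)
        assert np.allclose(ext[2:, 6], 2.0, atol=1e-9)

    def test_too_few_rows_raises(self):
        with pytest.raises(ValueError):
            extend_with_derivatives(np.zeros((2, 3)), 0.1)


class TestKfFit:
    def test_scalar_noiseless_ar_system(self):
        y = np.empty(100)
        y[0] = 1.0
        for k in range(1, 100):
            y[k] = 0.9 * y[k - 1]
        Y = y[:, None]
        X = Y.copy()
        # geometric decay is never zero-mean, so fit without centering
        params = kf_fit(X, Y, center=False)
        assert params.A[0, 0] == pytest.approx(0.9, abs=1e-10)
        assert params.W[0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_exact_linear_observation_recovers_h(self, rng):
        Y = rng.standard_normal((100, 3))
        H = rng.standard_normal((5, 3))
        X = Y @ H.T
        params = kf_fit(X, Y)
        assert np.allclose(params.H, H, atol=1e-10)
        assert np.allclose(params.Q, 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.standard_normal((200, 5))
        Y = rng.standard_normal((200, 3))
        p = kf_fit(X, Y)
        Xc = (X - X.mean(0)).T
        Yc = (Y - Y.mean(0)).T
        Y1, Y2 = Yc[:, :-1], Yc[:, 1:]
        A = Y2 @ Y1.T @ np.linalg.inv(Y1 @ Y1.T)
        H = Xc @ Yc.T @ np.linalg.inv(Yc @ Yc.T)
        W = (Y2 - A @ Y1) @ (Y2 - A @ Y1).T / 199
        Q = (Xc - H @ Yc) @ (Xc - H @ Yc).T / 200
        assert np.allclose(p.A, A, atol=1e-8)
        assert np.allclose(p.H, H, atol=1e-8)
        assert np.allclose(p.W, W, atol=1e-8)
        assert np.allclose(p.Q, Q, atol=1e-8)

    def test_consistency_on_simulated_system(self, rng):
        m, n = 3, 4
        A = 0.8 * np.eye(m) + 0.05 * rng.standard_normal((m, m))
        H = rng.standard_normal((n, m))
        W = 0.05 * np.eye(m)
        Q = 0.05 * np.eye(n)
        errs = []
        for N in (1000, 10000):
            X, Y = _simulate(rng, A, H, W, Q, N)
            p = kf_fit(X, Y)
            errs.append(np.linalg.norm(p.A - A) + np.linalg.norm(p.H - H))
        assert errs[1] < errs[0]
        assert errs[1] < 0.15

    def test_singular_moments_raise_with_jitter_advice(self):
        Y = np.zeros((50, 2))
        Y[:, 0] = np.arange(50.0)
        X = np.ones((50, 2))
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            kf_fit(X, Y)


class TestKfFilter:
    def test_perfect_observation_gain_is_identity(self, rng):
        m = 3
        params = KalmanParams(
            A=0.5 * np.eye(m), H=np.eye(m), W=np.eye(m), Q=np.zeros((m, m)),
            x_mean=np.zeros(m), y_mean=np.zeros(m),
        )
        X = rng.standard_normal((20, m))
        out = kf_filter(params, X)
        assert np.allclose(out, X, atol=1e-10)

    def test_scalar_steady_state_matches_riccati_closed_form(self):
        params = KalmanParams(
            A=np.eye(1), H=np.eye(1), W=np.eye(1), Q=np.eye(1),
            x_mean=np.zeros(1), y_mean=np.zeros(1),
        )
        golden = (1 + np.sqrt(5)) / 2          # prior variance fixed point
        K_expected = golden / (golden + 1)
        P = params.P0.copy()
        from smoothpls.kalman import _gain_step
        for _ in range(200):
            K, P = _gain_step(params, P, 0.0)
        assert K[0, 0] == pytest.approx(K_expected, abs=1e-8)

    def test_matches_reference_kalman_implementation(self, rng):
        m, n = 2, 3
        A = 0.7 * np.eye(m)
        H = rng.standard_normal((n, m))
        W = 0.1 * np.eye(m)
        Q = 0.2 * np.eye(n)
        params = KalmanParams(A=A, H=H, W=W, Q=Q,
                              x_mean=np.zeros(n), y_mean=np.zeros(m))
        X = rng.standard_normal((50, n))
        ours = kf_filter(params, X)
        ref = kalman_reference(A, H, W, Q, params.y0, params.P0, X)
        assert np.allclose(ours, ref, atol=1e-8)

    def test_near_perfect_observation_limit(self, rng):
        m = 3
        Hinv = rng.standard_normal((m, m)) + 3 * np.eye(m)
        params = KalmanParams(
            A=0.5 * np.eye(m), H=Hinv, W=np.eye(m), Q=1e-12 * np.eye(m),
            x_mean=np.zeros(m), y_mean=np.zeros(m),
        )
        X = rng.standard_normal((30, m))
        out = kf_filter(params, X)
        assert np.allclose(out, X @ np.linalg.inv(Hinv).T, atol=1e-5)

    def test_gain_converges_and_steady_state_agrees(self, rng):
        m, n = 3, 4
        A = 0.6 * np.eye(m) + 0.05 * rng.standard_normal((m, m))
        H = rng.standard_normal((n, m))
        W = 0.2 * np.eye(m)
        Q = 0.3 * np.eye(n)
        params = KalmanParams(A=A, H=H, W=W, Q=Q,
                              x_mean=np.zeros(n), y_mean=np.zeros(m))
        from smoothpls.kalman import _gain_step
        P = params.P0.copy()
        K_prev = None
        for k in range(500):
            K, P = _gain_step(params, P, 0.0)
            if K_prev is not None and np.max(np.abs(K - K_prev)) < 1e-8:
                break
            K_prev = K
        assert k < 500 - 1
        X = rng.standard_normal((600, n))
        per_step = kf_filter(params, X)
        cached = kf_filter(params, X, steady_state=True)
        assert np.allclose(per_step[100:], cached[100:], atol=1e-6)

    def test_information_form_matches_literal_recursion(self, rng):
        # wide observation (n >> m) triggers the information-form fast path
        m, n = 2, 12
        A = 0.7 * np.eye(m)
        H = rng.standard_normal((n, m))
        W = 0.1 * np.eye(m)
        Q = 0.5 * np.eye(n)
        params = KalmanParams(A=A, H=H, W=W, Q=Q,
                              x_mean=np.zeros(n), y_mean=np.zeros(m))
        X = rng.standard_normal((400, n))
        literal = kf_filter(params, X)
        fast = kf_filter(params, X, steady_state=True)
        assert np.allclose(literal[100:], fast[100:], atol=1e-6)

    def test_covariance_stays_symmetric_psd(self, rng):
        m, n = 3, 3
        A = 0.8 * np.eye(m)
        H = rng.standard_normal((n, m))
        W = 0.3 * np.eye(m)
        Q = 0.2 * np.eye(n)
        params = KalmanParams(A=A, H=H, W=W, Q=Q,
                              x_mean=np.zeros(n), y_mean=np.zeros(m))
        from smoothpls.kalman import _gain_step
        P = params.P0.copy()
        for _ in range(100):
            _, P = _gain_step(params, P, 0.0)
            assert np.allclose(P, P.T)
            assert np.linalg.eigvalsh(P).min() >= -1e-10
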