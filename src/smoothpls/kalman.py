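"""Kalman-filter trajectory decoder baseline.

The generative model couples a kinematic state ``y_k`` (positions, velocities
and accelerations; m = 9 for a 3-D trajectory) to the feature vector ``x_k``:

    y_{k+1} = A y_k + w_k,   w_k ~ N(0, W)
    x_k     = H y_k + q_k,   q_k ~ N(0, Q)

A, H and the noise covariances are identified from training data by least
squares on the centered streams (the state/observation equations carry no
intercept, so both are mean-centered first); decoding runs the standard
predict/update recursion.  For high-dimensional features the per-step n x n
innovation solve dominates, so a steady-state mode first iterates the gain
recursion to convergence and then filters with the fixed gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["KalmanParams", "extend_with_derivatives", "kf_fit", "kf_filter"]


@dataclass
class KalmanParams:
    A: np.ndarray          # (m, m) state transition
    H: np.ndarray          # (n, m) observation matrix
    W: np.ndarray          # (m, m) process-noise covariance
    Q: np.ndarray          # (n, n) observation-noise covariance
    x_mean: np.ndarray     # (n,) feature centering
    y_mean: np.ndarray     # (m,) state centering
    y0: Optional[np.ndarray] = None     # initial (centered) state
    P0: Optional[np.ndarray] = None     # initial covariance

    def __post_init__(self) -> None:
        m = self.A.shape[0]
        n = self.H.shape[0]
        if self.A.shape != (m, m) or self.H.shape != (n, m):
            raise ValueError("inconsistent A/H dimensions")
        if self.W.shape != (m, m) or self.Q.shape != (n, n):
            raise ValueError("inconsistent covariance dimensions")
        if self.y0 is None:
            self.y0 = np.zeros(m)
        if self.P0 is None:
            self.P0 = self.W.copy()

    @property
    def state_dim(self) -> int:
        return self.A.shape[0]

    @property
    def obs_dim(self) -> int:
        return self.H.shape[0]


def extend_with_derivatives(Y: np.ndarray, dt: float) -> np.ndarray:
    """Append velocity and acceleration columns to an (N, 3) trajectory.

    Derivatives are causal first differences divided by ``dt``, with the
    first row replicated so the output keeps N rows.  Column order is
    (positions, velocities, accelerations).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("trajectory must be 2-D")
    if Y.shape[0] < 3:
        raise ValueError("need at least 3 samples to form accelerations")
    vel = np.diff(Y, axis=0) / dt
    vel = np.vstack([vel[:1], vel])
    acc = np.diff(vel, axis=0) / dt
    acc = np.vstack([acc[:1], acc])
    return np.hstack([Y, vel, acc])


def _solve_gram(G: np.ndarray, rhs: np.ndarray, ridge: float, what: str):
    Gr = G + ridge * np.eye(G.shape[0]) if ridge > 0 else G
    cond = np.linalg.cond(Gr)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"{what} moment matrix is singular or near-singular; "
            "pass ridge > 0 to add diagonal jitter"
        )
    return np.linalg.solve(Gr, rhs)


def kf_fit(X: np.ndarray, Y: np.ndarray, ridge: float = 0.0,
           center: bool = True) -> KalmanParams:
    """Identify A, H, W, Q from aligned feature/state training streams.

    ``X`` is (N, n) features, ``Y`` (N, m) states.  Both are centered by
    their training means (the model equations carry no intercept; pass
    ``center=False`` for data that is zero-mean by construction); with
    lagged state blocks Y1 = y_1..y_{N-1} and
    Y2 = y_2..y_N the least-squares estimates are

        A = Y2 Y1' (Y1 Y1')^-1,  H = X Y' (Y Y')^-1,
        W = (Y2 - A Y1)(Y2 - A Y1)' / (N-1),  Q = (X - H Y)(X - H Y)' / N.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    N = X.shape[0]
    if Y.shape[0] != N:
        raise ValueError("X and Y lengths differ")
    n, m = X.shape[1], Y.shape[1]
    # Only the m x m state moment matrices are inverted here, so N > m + 1
    # suffices; with N <= n the estimated Q is rank-deficient, which surfaces
    # at filter time with the jitter advice.
    if N <= m + 1:
        raise ValueError("need N > m + 1 training samples")

    if center:
        x_mean = X.mean(axis=0)
        y_mean = Y.mean(axis=0)
    else:
        x_mean = np.zeros(n)
        y_mean = np.zeros(m)
    Xc = (X - x_mean).T          # (n, N)
    Yc = (Y - y_mean).T          # (m, N)
    Y1, Y2 = Yc[:, :-1], Yc[:, 1:]

    A = _solve_gram(Y1 @ Y1.T, (Y2 @ Y1.T).T, ridge, "state").T
    H = _solve_gram(Yc @ Yc.T, (Xc @ Yc.T).T, ridge, "observation").T
    Er = Y2 - A @ Y1
    W = Er @ Er.T / (N - 1)
    Eq = Xc - H @ Yc
    Q = Eq @ Eq.T / N
    W = (W + W.T) / 2
    Q = (Q + Q.T) / 2
    return KalmanParams(A=A, H=H, W=W, Q=Q, x_mean=x_mean, y_mean=y_mean)


def _gain_step(params: KalmanParams, P: np.ndarray, ridge: float):
    A, H, W, Q = params.A, params.H, params.W, params.Q
    P_prior = A @ P @ A.T + W
    S = H @ P_prior @ H.T + Q
    if ridge > 0:
        S = S + ridge * np.eye(S.shape[0])
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e14:
        raise np.linalg.LinAlgError(
            "innovation covariance is singular; pass innovation_ridge > 0"
        )
    K = np.linalg.solve(S.T, (P_prior @ H.T).T).T
    P_post = (np.eye(P.shape[0]) - K @ H) @ P_prior
    P_post = (P_post + P_post.T) / 2
    return K, P_post


def _steady_gain_information_form(params: KalmanParams, ridge: float,
                                  tol: float, max_iter: int) -> np.ndarray:
    """Converged gain via the information-form identity.

    ``K = P_prior H' (H P_prior H' + Q)^-1 = P_post H' Q^-1`` with
    ``P_post = (I + P_prior M)^-1 P_prior`` and ``M = H' Q^-1 H``: one n x n
    factorization of Q up front, then only m x m iterations — the same fixed
    point as the literal recursion, reached without per-step n x n solves.
    """
    import scipy.linalg

    A, H, W, Q = params.A, params.H, params.W, params.Q
    m = params.state_dim
    Qr = Q + ridge * np.eye(Q.shape[0]) if ridge > 0 else Q
    try:
        cho = scipy.linalg.cho_factor(Qr)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "observation-noise covariance is singular; pass innovation_ridge > 0"
        ) from e
    HtQinv = scipy.linalg.cho_solve(cho, H).T       # (m, n)
    M = HtQinv @ H                                  # (m, m)
    P_prior = A @ params.P0 @ A.T + W
    P_post_prev = None
    for _ in range(max_iter):
        P_post = np.linalg.solve(np.eye(m) + P_prior @ M, P_prior)
        P_post = (P_post + P_post.T) / 2
        if P_post_prev is not None and np.max(np.abs(P_post - P_post_prev)) < tol:
            break
        P_post_prev = P_post
        P_prior = A @ P_post @ A.T + W
    return P_post @ HtQinv


def kf_filter(params: KalmanParams, X_stream: np.ndarray, *,
              steady_state: bool = False, innovation_ridge: float = 0.0,
              gain_tol: float = 1e-10, max_gain_iter: int = 10000) -> np.ndarray:
    """Run the Kalman recursion over a feature stream; returns (N, m) states.

    With ``steady_state=True`` the covariance/gain recursion is first iterated
    (data-free) until the gain converges, then the whole stream is filtered
    with the fixed gain — an O(n m) per-step decoder for large n.
    """
    X_stream = np.asarray(X_stream, dtype=float)
    if X_stream.ndim != 2 or X_stream.shape[1] != params.obs_dim:
        raise ValueError("feature stream has wrong width")
    Xc = X_stream - params.x_mean
    A, H = params.A, params.H
    N, m = X_stream.shape[0], params.state_dim
    out = np.empty((N, m))
    y = params.y0.copy()

    if steady_state:
        if params.obs_dim > 4 * m:
            K = _steady_gain_information_form(
                params, innovation_ridge, gain_tol, max_gain_iter
            )
        else:
            P = params.P0.copy()
            K_prev = None
            for _ in range(max_gain_iter):
                K, P = _gain_step(params, P, innovation_ridge)
                if K_prev is not None and np.max(np.abs(K - K_prev)) < gain_tol:
                    break
                K_prev = K
        for k in range(N):
            y_prior = A @ y
            y = y_prior + K @ (Xc[k] - H @ y_prior)
            out[k] = y
    else:
        P = params.P0.copy()
        for k in range(N):
            y_prior = A @ y
            K, P = _gain_step(params, P, innovation_ridge)
            y = y_prior + K @ (Xc[k] - H @ y_prior)
            out[k] = y
    return out + params.y_mean
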