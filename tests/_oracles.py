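"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: the matrix PLS below is a
direct NIPALS-style loop on 2-D arrays, the rank-one oracle is plain
multi-restart alternating least squares, and the Kalman reference is the
textbook recursion written out with explicit inverses.
"""

from __future__ import annotations

import numpy as np


def _sign_fix(v):
    nz = np.flatnonzero(np.abs(v) > 1e-12 * max(1.0, np.abs(v).max()))
    return -v if len(nz) and v[nz[0]] < 0 else v


def matrix_pls_coefficients(X: np.ndarray, Y: np.ndarray, F: int) -> np.ndarray:
    """Generic matrix PLS (weight-vector deflation) coefficient matrix.

    Centers X and Y, extracts F factors with u initialised from the dominant
    left singular vector of the Y residual, deflates X by t w' and Y by its
    running prediction, and returns the (n, m) coefficient matrix acting on
    centered inputs.
    """
    Xr = X - X.mean(axis=0)
    Yr = Y - Y.mean(axis=0)
    N, n = Xr.shape
    m = Yr.shape[1]
    ws, qs, Ts, bs = [], [], [], []
    for _ in range(F):
        U, s, _ = np.linalg.svd(Yr, full_matrices=False)
        u = U[:, 0] * s[0]
        t = np.zeros(N)
        for _ in range(500):
            w = Xr.T @ u
            w = _sign_fix(w / np.linalg.norm(w))
            t_new = Xr @ w
            q = Yr.T @ t_new
            q = _sign_fix(q / np.linalg.norm(q))
            u = Yr @ q
            if np.linalg.norm(t_new - t) <= 1e-8 * max(1.0, np.linalg.norm(t_new)):
                t = t_new
                break
            t = t_new
        ws.append(w); qs.append(q); Ts.append(t)
        T = np.column_stack(Ts)
        b, *_ = np.linalg.lstsq(T, u, rcond=None)
        bs.append(b)
        Xr = Xr - np.outer(t, w)
        Yr = Yr - np.outer(T @ b, q)
    C = np.zeros((F, m))
    for f in range(F):
        C[: f + 1] += np.outer(bs[f], qs[f])
    W = np.column_stack(ws)
    R = np.zeros_like(W)
    for f in range(F):
        r = W[:, f].copy()
        if f:
            r -= R[:, :f] @ (W[:, :f].T @ W[:, f])
        R[:, f] = r
    return R @ C


def als_rank_one_objective(Z: np.ndarray, n_restarts: int = 100,
                           seed: int = 0, n_iter: int = 200) -> float:
    """Best <Z, w1 o w2 o w3> over multi-restart alternating least squares."""
    rng = np.random.default_rng(seed)
    d1, d2, d3 = Z.shape
    best = -np.inf
    for _ in range(n_restarts):
        w2 = rng.standard_normal(d2); w2 /= np.linalg.norm(w2)
        w3 = rng.standard_normal(d3); w3 /= np.linalg.norm(w3)
        for _ in range(n_iter):
            w1 = np.einsum("ijk,j,k->i", Z, w2, w3)
            w1 /= np.linalg.norm(w1)
            w2 = np.einsum("ijk,i,k->j", Z, w1, w3)
            w2 /= np.linalg.norm(w2)
            w3 = np.einsum("ijk,i,j->k", Z, w1, w2)
            nv = np.linalg.norm(w3)
            w3 /= nv
        best = max(best, abs(np.einsum("ijk,i,j,k->", Z, w1, w2, w3)))
    return best


def kalman_reference(A, H, W, Q, y0, P0, X):
    """Textbook predict/update recursion with explicit inverses."""
    y = y0.copy()
    P = P0.copy()
    out = np.empty((X.shape[0], len(y0)))
    I = np.eye(len(y0))
    for k in range(X.shape[0]):
        y_prior = A @ y
        P_prior = A @ P @ A.T + W
        S = H @ P_prior @ H.T + Q
        K = P_prior @ H.T @ np.linalg.inv(S)
        y = y_prior + K @ (X[k] - H @ y_prior)
        P = (I - K @ H) @ P_prior
        out[k] = y
    return out


def savgol_window_oracle(x: np.ndarray, p: int, l: int) -> np.ndarray:
    """Per-window polynomial least squares evaluated at the centre."""
    N = len(x)
    t = np.arange(-l, l + 1)
    V = np.vander(t, p + 1, increasing=True)
    out = []
    for i in range(l, N - l):
        coef, *_ = np.linalg.lstsq(V, x[i - l : i + l + 1], rcond=None)
        out.append(coef[0])
    return np.array(out)


def morlet_direct_conv(signal: np.ndarray, freqs, fs: float,
                       bandwidth: float, center: float) -> np.ndarray:
    """Direct convolution with the sampled analytic Morlet kernel.

    Returns |coefficients| of shape (len(freqs), len(signal)) using an
    L2-normalised kernel psi_a(t) = a^-1/2 (pi B)^-1/4-free amplitude
    convention; only used for argmax-location comparisons, where the
    constant amplitude factor is irrelevant.
    """
    out = np.empty((len(freqs), len(signal)))
    for i, f in enumerate(freqs):
        a = center * fs / f
        half = int(np.ceil(8 * a))
        t = np.arange(-half, half + 1) / a
        psi = np.exp(-t**2 / bandwidth) * np.exp(2j * np.pi * center * t)
        psi /= np.sqrt(a)
        from scipy.signal import fftconvolve
        coef = fftconvolve(signal.astype(complex), np.conj(psi[::-1]),
                           mode="same")
        out[i] = np.abs(coef)
    return out
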