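"""Multi-way (N-way) partial least squares regression for 4-way predictors.

The model links a tensor of observations ``X`` (epochs x d1 x d2 x d3) to a
response matrix ``Y`` (epochs x m) through ``F`` latent factors.  Each factor
``f`` carries a rank-one weight tensor ``w1_f o w2_f o w3_f`` (unit-norm mode
projectors), a score vector ``t_f`` (the contraction of the current X residual
with the weight tensor), a unit-norm response loading ``q_f`` and inner
regression coefficients ``b_f`` regressing the response scores ``u_f`` on all
scores extracted so far:

    X = sum_f t_f o w1_f o w2_f o w3_f + E,    u_f = T_f b_f,
    Y = sum_f (T_f b_f) q_f^T + F_resid.

Residuals are deflated per factor: X by the rank-one component
``t_f o w1_f o w2_f o w3_f`` and Y by its running prediction.  Generic matrix
PLS is the special case where modes 2 and 3 are singletons.

Conventions making fits reproducible:

* X and Y are mean-centered on training data; no variance scaling.
* ``u`` is initialised from the dominant left singular vector of the current
  Y residual (deterministic, no column-order dependence).
* The first nonzero entry of every projector (and of ``q_f``) is made
  positive; the score signs absorb the flips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np

from .features import EpochFeatureTensor, TrajectoryMatrix

__all__ = ["NplsModel", "rank_one_approx", "npls_fit", "npls_predict",
           "materialize_coefficients"]

_RANK1_TOL = 1e-10
_RANK1_MAXIT = 500
_SCORE_TOL = 1e-8
_SCORE_MAXIT = 500
_EPS = 1e-12


def _as_tensor(X) -> np.ndarray:
    if isinstance(X, EpochFeatureTensor):
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 4:
        raise ValueError("predictor block must be 4-way (obs x d1 x d2 x d3)")
    return X


def _as_response(Y) -> np.ndarray:
    if isinstance(Y, TrajectoryMatrix):
        Y = Y.values
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.ndim != 2 or Y.shape[1] < 1:
        raise ValueError("response must be a matrix with >= 1 column")
    return Y


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Flip ``v`` so its first non-negligible entry is positive."""
    nz = np.flatnonzero(np.abs(v) > _EPS * max(1.0, np.abs(v).max()))
    if len(nz) and v[nz[0]] < 0:
        return -v
    return v


@dataclass
class NplsModel:
    """Fitted multi-way PLS decoder.

    ``W1, W2, W3`` hold the per-factor mode projectors as columns;
    ``Q`` the response loadings; ``B_inner`` the inner-regression
    coefficients (``B_inner[f]`` has length ``f+1``: triangular by
    construction); ``B_full`` the materialised coefficient tensor
    (d1 x d2 x d3 x m) acting on centered inputs.
    """

    n_factors: int
    W1: np.ndarray
    W2: np.ndarray
    W3: np.ndarray
    Q: np.ndarray
    B_inner: list
    T_scores: np.ndarray
    U_scores: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    B_full: np.ndarray
    residual_norms: dict = field(default_factory=dict)
    truncated: bool = False

    @property
    def mode_shape(self) -> tuple:
        return self.x_mean.shape

    @property
    def n_responses(self) -> int:
        return len(self.y_mean)

    @property
    def w_vectors(self) -> np.ndarray:
        """Vectorised rank-one weight tensors, one column per factor."""
        n = int(np.prod(self.mode_shape))
        W = np.empty((n, self.n_factors))
        for f in range(self.n_factors):
            W[:, f] = np.einsum(
                "i,j,k->ijk", self.W1[:, f], self.W2[:, f], self.W3[:, f]
            ).ravel()
        return W

    @property
    def inner_coef_matrix(self) -> np.ndarray:
        """C (F x m) with prediction ``Y_hat = T @ C + y_mean``."""
        F, m = self.n_factors, self.n_responses
        C = np.zeros((F, m))
        for f in range(F):
            C[: f + 1] += np.outer(self.B_inner[f], self.Q[:, f])
        return C


def rank_one_approx(Z: np.ndarray, tol: float = _RANK1_TOL,
                    max_iter: int = _RANK1_MAXIT) -> tuple:
    """Dominant rank-one approximation of a 3-way block.

    Returns unit-norm ``(w1, w2, w3)`` maximising ``<Z, w1 o w2 o w3>``
    (up to the sign convention; the caller's score absorbs the sign), via
    higher-order power iteration initialised from the dominant singular
    vectors of the mode unfoldings.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 3:
        raise ValueError("Z must be 3-way")
    if not np.all(np.isfinite(Z)):
        raise ValueError("Z contains non-finite values")
    if not np.any(Z):
        raise ValueError("degenerate factor: all-zero block")

    def _dominant(unfold: np.ndarray) -> np.ndarray:
        u, _, _ = np.linalg.svd(unfold, full_matrices=False)
        return u[:, 0]

    d1, d2, d3 = Z.shape
    w1 = _dominant(Z.reshape(d1, -1))
    w2 = _dominant(Z.transpose(1, 0, 2).reshape(d2, -1))
    w3 = _dominant(Z.transpose(2, 0, 1).reshape(d3, -1))

    obj_prev = np.einsum("ijk,i,j,k->", Z, w1, w2, w3)
    for _ in range(max_iter):
        v = np.einsum("ijk,j,k->i", Z, w2, w3)
        w1 = v / np.linalg.norm(v)
        v = np.einsum("ijk,i,k->j", Z, w1, w3)
        w2 = v / np.linalg.norm(v)
        v = np.einsum("ijk,i,j->k", Z, w1, w2)
        nv = np.linalg.norm(v)
        w3 = v / nv
        if abs(nv - abs(obj_prev)) <= tol * max(1.0, abs(nv)):
            obj_prev = nv
            break
        obj_prev = nv
    return _fix_sign(w1), _fix_sign(w2), _fix_sign(w3)


def npls_fit(X, Y, n_factors: int, *, center: bool = True,
             tol: float = _SCORE_TOL, max_iter: int = _SCORE_MAXIT) -> NplsModel:
    """Fit an N-way PLS model with ``n_factors`` latent factors.

    With ``center=False`` the caller guarantees X and Y are already centered
    (used by the penalised variants, whose augmented zero rows must stay
    zero).  A degenerate factor (all-zero residual contraction or score)
    truncates the model with a warning.
    """
    X = _as_tensor(X)
    Y = _as_response(Y)
    N, d1, d2, d3 = X.shape
    if Y.shape[0] != N:
        raise ValueError("X and Y observation counts differ")
    if n_factors < 0:
        raise ValueError("n_factors must be >= 0")
    if n_factors > 0 and N < n_factors + 1:
        raise ValueError("need at least n_factors + 1 observations")

    x_mean = X.mean(axis=0) if center else np.zeros((d1, d2, d3))
    y_mean = Y.mean(axis=0) if center else np.zeros(Y.shape[1])
    Xr = X - x_mean
    Yr = Y - y_mean
    m = Y.shape[1]

    W1 = np.zeros((d1, 0)); W2 = np.zeros((d2, 0)); W3 = np.zeros((d3, 0))
    Qm = np.zeros((m, 0))
    Ts: list = []; Us: list = []; B_inner: list = []
    truncated = False

    for f in range(n_factors):
        Uy, sy, _ = np.linalg.svd(Yr, full_matrices=False)
        if sy[0] <= _EPS:
            truncated = True
            warnings.warn(f"response residual exhausted after {f} factors",
                          RuntimeWarning, stacklevel=2)
            break
        u = Uy[:, 0] * sy[0]

        w1 = w2 = w3 = None
        t = np.zeros(N)
        degenerate = False
        for _ in range(max_iter):
            Z = np.einsum("nijk,n->ijk", Xr, u)
            if not np.any(np.abs(Z) > _EPS):
                degenerate = True
                break
            w1, w2, w3 = rank_one_approx(Z)
            t_new = np.einsum("nijk,i,j,k->n", Xr, w1, w2, w3)
            q = Yr.T @ t_new
            nq = np.linalg.norm(q)
            if nq <= _EPS:
                degenerate = True
                break
            q = _fix_sign(q / nq)
            u = Yr @ q
            delta = np.linalg.norm(t_new - t)
            t = t_new
            if delta <= tol * max(1.0, np.linalg.norm(t)):
                break
        if degenerate or np.linalg.norm(t) <= _EPS:
            truncated = True
            warnings.warn(f"degenerate factor at f={f}; model truncated",
                          RuntimeWarning, stacklevel=2)
            break

        Ts.append(t); Us.append(u)
        W1 = np.column_stack([W1, w1]); W2 = np.column_stack([W2, w2])
        W3 = np.column_stack([W3, w3]); Qm = np.column_stack([Qm, q])
        Tmat = np.column_stack(Ts)
        b, *_ = np.linalg.lstsq(Tmat, u, rcond=None)
        B_inner.append(b)

        Xr = Xr - np.einsum("n,i,j,k->nijk", t, w1, w2, w3)
        Yr = Yr - np.outer(Tmat @ b, q)

    F_eff = len(Ts)
    T_scores = np.column_stack(Ts) if Ts else np.zeros((N, 0))
    U_scores = np.column_stack(Us) if Us else np.zeros((N, 0))
    model = NplsModel(
        n_factors=F_eff, W1=W1, W2=W2, W3=W3, Q=Qm, B_inner=B_inner,
        T_scores=T_scores, U_scores=U_scores,
        x_mean=x_mean, y_mean=y_mean,
        B_full=np.zeros((d1, d2, d3, m)),
        residual_norms={
            "x": float(np.linalg.norm(Xr)),
            "y": float(np.linalg.norm(Yr)),
        },
        truncated=truncated,
    )
    model.B_full = materialize_coefficients(model)
    return model


def materialize_coefficients(model: NplsModel) -> np.ndarray:
    """Coefficient tensor ``B`` (d1 x d2 x d3 x m) of the fitted linear map.

    Prediction on a centered input x is ``<B, x> + y_mean`` for every sample.
    Computed from the effective score weights: with vectorised rank-one
    weights ``w_f`` and X-deflation by ``t_f w_f^T``, scores satisfy
    ``t_f = X_c r_f`` with ``r_f = w_f - sum_{g<f} (w_g . w_f) r_g``, hence
    ``B = R C`` with C the accumulated inner-regression/loading matrix.
    """
    shape = model.mode_shape + (model.n_responses,)
    if model.n_factors == 0:
        return np.zeros(shape)
    W = model.w_vectors
    n, F = W.shape
    R = np.zeros((n, F))
    for f in range(F):
        r = W[:, f].copy()
        if f:
            r -= R[:, :f] @ (W[:, :f].T @ W[:, f])
        R[:, f] = r
    B = R @ model.inner_coef_matrix
    return B.reshape(shape)


def npls_predict(model: NplsModel, X) -> np.ndarray:
    """Predict responses for new epochs (returns an (N, m) array)."""
    X = _as_tensor(X)
    if X.shape[1:] != model.mode_shape:
        raise ValueError(
            f"mode shape {X.shape[1:]} does not match model {model.mode_shape}"
        )
    N = X.shape[0]
    Xc = (X - model.x_mean).reshape(N, -1)
    if model.n_factors == 0:
        return np.tile(model.y_mean, (N, 1))
    W = model.w_vectors
    T = np.empty((N, model.n_factors))
    for f in range(model.n_factors):
        t = Xc @ W[:, f]
        T[:, f] = t
        Xc = Xc - np.outer(t, W[:, f])
    return T @ model.inner_coef_matrix + model.y_mean
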