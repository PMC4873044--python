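"""Smoothness penalties for multi-way PLS via data augmentation.

Both penalised decoders reduce to ordinary least-squares-style augmentation:
the penalty ``lambda * ||B x_extra||^2`` is realised by stacking extra
pseudo-observations ``lambda * X_extra`` under the (centered) predictor block
with zero responses, and fitting plain N-way PLS to the augmented pair.

* Sobolev variant (SNPLS): the extra block is the s-th order finite
  difference of the feature stream along the observation axis, penalising the
  s-th derivative of the predicted trajectory (a Sobolev-norm objective).
* Polynomial variant (PNPLS): the extra block is the residual of a sliding
  Savitzky-Golay polynomial smoother (degree ``p``, window ``2l+1``),
  penalising the difference between predictions on raw and smoothed features.

Centering happens *before* augmentation so the zero response block stays
exactly zero; this makes the ``lambda = 0`` case coincide with plain NPLS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import savgol_coeffs

from .npls import NplsModel, _as_response, _as_tensor, npls_fit

__all__ = [
    "PenaltyConfig",
    "finite_difference",
    "polynomial_smooth",
    "augment_sobolev",
    "augment_polynomial",
    "snpls_fit",
    "pnpls_fit",
]


@dataclass(frozen=True)
class PenaltyConfig:
    """Penalty hyper-parameters.

    ``lam`` scales the penalty block; ``variant`` selects the Sobolev
    (derivative order ``s``, default 3) or polynomial (degree ``p`` = 2,
    half-window ``l`` = 4, i.e. window L = 9) flavour.
    """

    lam: float
    variant: str = "sobolev"
    s: int = 3
    p: int = 2
    l: int = 4

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if self.variant not in ("sobolev", "polynomial"):
            raise ValueError("variant must be 'sobolev' or 'polynomial'")
        if self.s < 1:
            raise ValueError("derivative order s must be >= 1")
        if self.p < 0:
            raise ValueError("polynomial degree p must be >= 0")
        if self.l < 1:
            raise ValueError("half-window l must be >= 1")
        if 2 * self.l + 1 <= self.p + 1:
            raise ValueError("window 2l+1 must exceed p+1 for a solvable fit")


def finite_difference(X: np.ndarray, s: int) -> np.ndarray:
    """s-fold iterated first difference along the observation axis.

    Output row ``i`` is the backward s-th difference ending at observation
    ``i + s``; no time-step scaling is applied (lambda absorbs it).
    """
    X = np.asarray(X, dtype=float)
    if s < 1:
        raise ValueError("s must be >= 1")
    if X.shape[0] <= s:
        raise ValueError(f"need more than s={s} observations, got {X.shape[0]}")
    return np.diff(X, n=s, axis=0)


def polynomial_smooth(X: np.ndarray, p: int, l: int) -> np.ndarray:
    """Sliding-window least-squares polynomial (Savitzky-Golay) smoother.

    For each feature independently, fits a degree-``p`` polynomial to each
    window of ``2l+1`` consecutive observations and evaluates it at the
    window centre.  Only the valid centre rows ``l .. N-l-1`` (0-based) are
    returned, shape ``(N - 2l, ...)``.
    """
    X = np.asarray(X, dtype=float)
    L = 2 * l + 1
    N = X.shape[0]
    if N < L:
        raise ValueError(f"need at least {L} observations, got {N}")
    # savgol_coeffs returns convolution coefficients; reverse for a direct
    # dot with the window in natural order (symmetric for deriv=0, but kept
    # explicit).
    kernel = savgol_coeffs(L, p)[::-1].copy()
    windows = sliding_window_view(X, L, axis=0)  # (N-2l, ..., L)
    return windows @ kernel


def _flatten(X: np.ndarray):
    shape = X.shape
    return X.reshape(shape[0], -1), shape[1:]


def augment_sobolev(Xc, Yc, lam: float, s: int = 3):
    """Stack the scaled s-th difference block under centered data.

    Inputs must already be centered by the caller.  Returns the augmented
    tensor (N + N - s rows) and response matrix whose lower block is zero.
    """
    Xc = _as_tensor(Xc)
    Yc = _as_response(Yc)
    flat, modes = _flatten(Xc)
    diff = finite_difference(flat, s)
    X_aug = np.concatenate([flat, lam * diff], axis=0)
    Y_aug = np.concatenate([Yc, np.zeros((diff.shape[0], Yc.shape[1]))], axis=0)
    return X_aug.reshape((-1,) + modes), Y_aug


def augment_polynomial(Xc, Yc, lam: float, p: int = 2, l: int = 4):
    """Stack the scaled smoother-residual block under centered data.

    The block is ``lam * (Xc - smooth(Xc))`` on the ``N - 2l`` valid window
    centres; features that are exactly degree-``p`` polynomials of the epoch
    index contribute zero penalty.
    """
    Xc = _as_tensor(Xc)
    Yc = _as_response(Yc)
    flat, modes = _flatten(Xc)
    smooth = polynomial_smooth(flat, p, l)
    resid = flat[l : flat.shape[0] - l] - smooth
    X_aug = np.concatenate([flat, lam * resid], axis=0)
    Y_aug = np.concatenate([Yc, np.zeros((resid.shape[0], Yc.shape[1]))], axis=0)
    return X_aug.reshape((-1,) + modes), Y_aug


def _penalized_fit(X, Y, n_factors: int, cfg: PenaltyConfig) -> NplsModel:
    X = _as_tensor(X)
    Y = _as_response(Y)
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    if cfg.variant == "sobolev":
        X_aug, Y_aug = augment_sobolev(Xc, Yc, cfg.lam, cfg.s)
    else:
        X_aug, Y_aug = augment_polynomial(Xc, Yc, cfg.lam, cfg.p, cfg.l)
    model = npls_fit(X_aug, Y_aug, n_factors, center=False)
    # restore the training means so prediction re-centers new data correctly
    model.x_mean = x_mean
    model.y_mean = y_mean
    return model


def snpls_fit(X, Y, n_factors: int, lam: float, s: int = 3) -> NplsModel:
    """Sobolev-penalised N-way PLS (derivative-order smoothness penalty)."""
    return _penalized_fit(X, Y, n_factors,
                          PenaltyConfig(lam=lam, variant="sobolev", s=s))


def pnpls_fit(X, Y, n_factors: int, lam: float, p: int = 2, l: int = 4) -> NplsModel:
    """Polynomial-penalised N-way PLS (Savitzky-Golay residual penalty)."""
    return _penalized_fit(X, Y, n_factors,
                          PenaltyConfig(lam=lam, variant="polynomial", p=p, l=l))
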