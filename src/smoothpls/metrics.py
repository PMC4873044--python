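"""Prediction-quality criteria, delay estimation and modality influence.

Accuracy criteria compare an observed trajectory ``y`` with a prediction
``y_hat``:

    r    = Pearson correlation(y, y_hat)
    RMSE = ||y - y_hat||_2 / ||y - mean(y)||_2
    MAE  = ||y - y_hat||_1 / ||y - mean(y)||_1
    MADE = ||y' - y_hat'||_1 / ||y' - mean(y')||_1

with ``y'`` the first-difference sequence; MADE measures joint accuracy and
smoothness.  The RMSE/MAE normalisers are the centered-observation norms (a
mean predictor scores exactly 1), not per-sample averages.

The prediction delay is the minimal non-negative shift of the predicted
signal that maximises its correlation with the observed one, scanned on the
prediction-rate grid over a configurable interval (default [0, 2] s).

Modality influence summarises a coefficient tensor: per modality
(frequency / temporal lag / channel), each element's weight is the sum of
absolute coefficients over all other indices, normalised to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MetricsReport", "DelayEstimate", "InfluenceProfile",
    "pearson", "rmse_norm", "mae_norm", "made",
    "estimate_delay", "delay_report", "modality_influence", "anova_compare",
]

_TIE_TOL = 1e-12


def _vec(y) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    return y


def pearson(y, y_hat) -> float:
    """Sample Pearson correlation; errors on constant inputs."""
    y, y_hat = _vec(y), _vec(y_hat)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch")
    yc = y - y.mean()
    hc = y_hat - y_hat.mean()
    ny, nh = np.linalg.norm(yc), np.linalg.norm(hc)
    if ny == 0 or nh == 0:
        raise ValueError("correlation undefined for constant input")
    return float(yc @ hc / (ny * nh))


def rmse_norm(y, y_hat) -> float:
    """L2 error normalised by the centered-observation L2 norm."""
    y, y_hat = _vec(y), _vec(y_hat)
    denom = np.linalg.norm(y - y.mean())
    if denom == 0:
        raise ValueError("normaliser undefined for constant y")
    return float(np.linalg.norm(y - y_hat) / denom)


def mae_norm(y, y_hat) -> float:
    """L1 error normalised by the centered-observation L1 norm."""
    y, y_hat = _vec(y), _vec(y_hat)
    denom = np.abs(y - y.mean()).sum()
    if denom == 0:
        raise ValueError("normaliser undefined for constant y")
    return float(np.abs(y - y_hat).sum() / denom)


def made(y, y_hat) -> float:
    """Mean absolute differential error: ``mae_norm`` of first differences."""
    y, y_hat = _vec(y), _vec(y_hat)
    return mae_norm(np.diff(y), np.diff(y_hat))


@dataclass
class MetricsReport:
    """Per-coordinate criteria plus their equal-weight averages."""

    r: np.ndarray
    rmse: np.ndarray
    mae: np.ndarray
    made: np.ndarray

    @classmethod
    def compute(cls, Y, Y_hat) -> "MetricsReport":
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        Y_hat = np.atleast_2d(np.asarray(Y_hat, dtype=float))
        if Y.shape != Y_hat.shape:
            raise ValueError("shape mismatch")
        cols = range(Y.shape[1])
        return cls(
            r=np.array([pearson(Y[:, j], Y_hat[:, j]) for j in cols]),
            rmse=np.array([rmse_norm(Y[:, j], Y_hat[:, j]) for j in cols]),
            mae=np.array([mae_norm(Y[:, j], Y_hat[:, j]) for j in cols]),
            made=np.array([made(Y[:, j], Y_hat[:, j]) for j in cols]),
        )

    @property
    def mean_r(self) -> float:
        return float(self.r.mean())

    @property
    def mean_rmse(self) -> float:
        return float(self.rmse.mean())

    @property
    def mean_mae(self) -> float:
        return float(self.mae.mean())

    @property
    def mean_made(self) -> float:
        return float(self.made.mean())

    def to_dict(self) -> dict:
        return {
            "per_coordinate": {
                "r": self.r.tolist(), "rmse": self.rmse.tolist(),
                "mae": self.mae.tolist(), "made": self.made.tolist(),
            },
            "mean": {
                "r": self.mean_r, "rmse": self.mean_rmse,
                "mae": self.mean_mae, "made": self.mean_made,
            },
        }


@dataclass
class DelayEstimate:
    delay: float
    correlation: float
    s_max: float


def estimate_delay(y, y_hat, dt: float, s_max: float = 2.0) -> DelayEstimate:
    """Minimal shift of the prediction maximising correlation with ``y``.

    Shifts are multiples of ``dt`` in ``[0, s_max]``; shifting by ``k``
    correlates ``y[:-k]`` with ``y_hat[k:]`` (the prediction advanced in
    time).  Among shifts tying at the maximum, the smallest is returned.
    """
    y, y_hat = _vec(y), _vec(y_hat)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch")
    if dt <= 0 or s_max < 0:
        raise ValueError("dt must be positive and s_max non-negative")
    k_max = int(round(s_max / dt))
    if len(y) - k_max < 2:
        raise ValueError("overlap shorter than 2 samples at the largest shift")
    corrs = np.full(k_max + 1, -np.inf)
    for k in range(k_max + 1):
        a = y[: len(y) - k] if k else y
        b = y_hat[k:]
        try:
            corrs[k] = pearson(a, b)
        except ValueError:
            continue
    best = corrs.max()
    if not np.isfinite(best):
        raise ValueError("correlation undefined at every shift")
    k_star = int(np.flatnonzero(corrs >= best - _TIE_TOL)[0])
    return DelayEstimate(delay=k_star * dt, correlation=float(corrs[k_star]),
                         s_max=s_max)


def delay_report(Y, Y_hat, dt: float, s_max: float = 2.0) -> dict:
    """Per-coordinate delays and their mean (equal weighting)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    Y_hat = np.atleast_2d(np.asarray(Y_hat, dtype=float))
    ests = [estimate_delay(Y[:, j], Y_hat[:, j], dt, s_max)
            for j in range(Y.shape[1])]
    return {
        "per_coordinate": [e.delay for e in ests],
        "correlation_at_delay": [e.correlation for e in ests],
        "mean_delay": float(np.mean([e.delay for e in ests])),
        "s_max": s_max,
    }


@dataclass
class InfluenceProfile:
    """Normalised absolute-coefficient mass per modality element."""

    frequency: np.ndarray
    temporal: np.ndarray
    spatial: np.ndarray

    def to_dict(self) -> dict:
        return {"frequency": self.frequency.tolist(),
                "temporal": self.temporal.tolist(),
                "spatial": self.spatial.tolist()}


def modality_influence(B_full: np.ndarray) -> InfluenceProfile:
    """Influence weights from a (freq, lag, channel, m) coefficient tensor."""
    B = np.asarray(B_full, dtype=float)
    if B.ndim != 4:
        raise ValueError("coefficient block must be 4-way (freq, lag, chan, m)")
    absB = np.abs(B)
    total = absB.sum()
    if total == 0:
        raise ValueError("influence undefined for all-zero coefficients")
    return InfluenceProfile(
        frequency=absB.sum(axis=(1, 2, 3)) / total,
        temporal=absB.sum(axis=(0, 2, 3)) / total,
        spatial=absB.sum(axis=(0, 1, 3)) / total,
    )


def anova_compare(values_a, values_b) -> float:
    """One-way ANOVA p-value between two per-recording criterion samples.

    Thin evaluation helper for method comparison at a chosen significance
    level (0.05 by convention here).
    """
    _, p = stats.f_oneway(np.asarray(values_a, float), np.asarray(values_b, float))
    return float(p)
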