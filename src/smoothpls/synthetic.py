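"""Seeded synthetic data with the structure the decoders assume.

Three generators, all pure functions of (config, seed):

* ``gen_trajectory`` — 3-D trajectories as low-pass-filtered Gaussian noise,
  standardized per coordinate; emulates slow reaching movements relative to
  the epoch rate.
* ``gen_feature_tensor`` — a 4-way feature tensor carrying a planted
  low-rank linear relationship to the trajectory: R rank-one factors whose
  scores are fixed linear combinations of the coordinates, plus AR(1)
  epoch-level noise scaled to a target signal-to-noise ratio.  The AR
  coefficient controls how *unsmooth* the noise is — smoothness penalties
  only help when the noise breaks the temporal smoothness of the stream.
* ``gen_raw_recording`` — band-modulated oscillatory multichannel signals:
  informative channels carry a carrier sinusoid amplitude-modulated by one
  trajectory coordinate on top of 1/f background noise, for end-to-end tests
  of the feature-extraction stage.

What these generators do *not* emulate: non-stationarity, cross-channel
correlation structure, movement artifacts, or realistic ECoG spectra beyond
the 1/f background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .features import EpochFeatureTensor, TrajectoryMatrix

__all__ = ["SyntheticConfig", "gen_trajectory", "gen_feature_tensor",
           "gen_raw_recording"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    ``dims`` are the (frequency, lag, channel) mode sizes of the feature
    tensor; ``snr`` is the signal-to-noise variance ratio (``inf`` disables
    noise); ``noise_ar`` the AR(1) coefficient of the epoch-level noise.
    Raw-signal options: informative channels 0..2 carry carriers modulated
    by trajectory coordinates x, y, z respectively.
    """

    n_epochs: int = 2000
    dt: float = 0.1
    cutoff_hz: float = 1.0
    n_factors: int = 3
    dims: tuple = (15, 10, 64)
    snr: float = 1.0
    noise_ar: float = 0.3
    #: optional singular values of the factor/coordinate mixing matrix;
    #: decaying values make the planted factor streams partially collinear
    #: (harder to separate), None draws unit-norm random rows
    mixing_singular_values: Optional[tuple] = None
    # raw-recording options
    n_channels: int = 8
    sampling_rate: float = 1000.0
    carriers_hz: Sequence[float] = (30.0, 60.0, 90.0)
    modulation_depth: float = 0.5
    background_level: float = 0.25
    epoch_length: float = 1.0

    def __post_init__(self) -> None:
        if self.n_epochs < 20:
            raise ValueError("need at least 20 epochs")
        if not (self.snr > 0):
            raise ValueError("snr must be positive")
        if not (0 <= self.noise_ar < 1):
            raise ValueError("noise_ar must lie in [0, 1)")
        if self.cutoff_hz >= 0.5 / self.dt:
            raise ValueError("trajectory cutoff must lie below Nyquist of 1/dt")
        if self.sampling_rate < 2 * max(self.carriers_hz):
            raise ValueError("sampling rate below twice the top carrier")


def gen_trajectory(cfg: SyntheticConfig, seed: int) -> TrajectoryMatrix:
    """Low-pass-filtered Gaussian 3-D trajectory, standardized per coordinate.

    Timestamps start at ``epoch_length`` so the trajectory pairs directly
    with epochs ending on the same grid.
    """
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((cfg.n_epochs, 3))
    fs = 1.0 / cfg.dt
    # Chebyshev-II places the stopband edge at the cutoff itself, so the
    # generated coordinates carry essentially no power above it
    sos = signal.cheby2(6, 40, cfg.cutoff_hz / (fs / 2), output="sos")
    traj = signal.sosfiltfilt(sos, white, axis=0)
    traj = traj - traj.mean(axis=0)
    traj = traj / traj.std(axis=0)
    times = cfg.epoch_length + np.arange(cfg.n_epochs) * cfg.dt
    return TrajectoryMatrix(values=traj, times=times)


def _planted_factors(cfg: SyntheticConfig, rng: np.random.Generator):
    """Unit-norm mode projectors and a coordinate mixing matrix."""
    if cfg.n_factors > min(cfg.dims):
        raise ValueError("n_factors exceeds a mode dimension")
    # Per-mode projectors are orthonormal across factors (QR of a seeded
    # Gaussian draw): with mutually orthogonal rank-one components the
    # dominant-component extraction of the decoder can identify the planted
    # factors exactly, which the recovery tests rely on.
    per_mode = []
    for d in cfg.dims:
        Qm, _ = np.linalg.qr(rng.standard_normal((d, cfg.n_factors)))
        per_mode.append(Qm)
    projectors = [tuple(per_mode[m][:, r] for m in range(3))
                  for r in range(cfg.n_factors)]
    if cfg.mixing_singular_values is not None:
        sv = np.asarray(cfg.mixing_singular_values, dtype=float)
        if len(sv) != min(cfg.n_factors, 3):
            raise ValueError("need min(n_factors, 3) mixing singular values")
        U, _ = np.linalg.qr(rng.standard_normal((cfg.n_factors, len(sv))))
        V, _ = np.linalg.qr(rng.standard_normal((3, len(sv))))
        mixing = (U * sv) @ V.T
    else:
        mixing = rng.standard_normal((cfg.n_factors, 3))
        mixing /= np.linalg.norm(mixing, axis=1, keepdims=True)
    return projectors, mixing


def gen_feature_tensor(traj: TrajectoryMatrix, cfg: SyntheticConfig,
                       seed: int) -> EpochFeatureTensor:
    """Feature tensor X = sum_r c_r(traj) * (w1_r o w2_r o w3_r) + AR(1) noise."""
    rng = np.random.default_rng(seed)
    projectors, mixing = _planted_factors(cfg, rng)
    N = traj.n_samples
    d1, d2, d3 = cfg.dims
    scores = traj.values @ mixing.T          # (N, R)
    X = np.zeros((N, d1, d2, d3))
    for r, (w1, w2, w3) in enumerate(projectors):
        X += np.einsum("n,i,j,k->nijk", scores[:, r], w1, w2, w3)
    sig_var = X.var()

    if np.isfinite(cfg.snr):
        phi = cfg.noise_ar
        innov = rng.standard_normal((N, d1, d2, d3))
        noise = np.empty_like(innov)
        noise[0] = innov[0]
        scale = np.sqrt(1 - phi**2)
        for i in range(1, N):
            noise[i] = phi * noise[i - 1] + scale * innov[i]
        noise *= np.sqrt(sig_var / cfg.snr)
        X += noise

    width = cfg.epoch_length / d2
    return EpochFeatureTensor(
        values=X,
        epoch_times=traj.times,
        freq_hz=10.0 * (1 + np.arange(d1)),
        lag_s=-cfg.epoch_length + (np.arange(d2) + 0.5) * width,
        channel_ids=np.arange(d3),
    )


def planted_projectors(cfg: SyntheticConfig, seed: int):
    """The (projectors, mixing) pair ``gen_feature_tensor`` plants for ``seed``."""
    rng = np.random.default_rng(seed)
    return _planted_factors(cfg, rng)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n)
    shape = np.ones_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spec * shape, n)
    return x / x.std()


def gen_raw_recording(traj: TrajectoryMatrix, cfg: SyntheticConfig,
                      seed: int) -> np.ndarray:
    """Multichannel oscillatory recording driven by the trajectory.

    Channel ``b < 3``: ``(1 + depth * m_b(t)) * sin(2 pi f_b t + phase)``
    plus 1/f background, where ``m_b`` is coordinate ``b`` of the trajectory
    interpolated to the sampling rate.  Remaining channels are background
    noise only.  The recording covers ``[0, traj.times[-1]]``.
    """
    rng = np.random.default_rng(seed)
    fs = cfg.sampling_rate
    n_samples = int(round(traj.times[-1] * fs))
    t = np.arange(n_samples) / fs
    rec = np.empty((cfg.n_channels, n_samples))
    for c in range(cfg.n_channels):
        rec[c] = cfg.background_level * _pink_noise(rng, n_samples)
        if c < min(3, len(cfg.carriers_hz)):
            mod = np.interp(t, traj.times, traj.values[:, c])
            phase = rng.uniform(0, 2 * np.pi)
            rec[c] += (1 + cfg.modulation_depth * mod) * np.sin(
                2 * np.pi * cfg.carriers_hz[c] * t + phase
            )
    return rec
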