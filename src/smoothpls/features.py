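"""Time-frequency feature extraction for continuous trajectory decoding.

A multichannel recording is cut into overlapping epochs of length ``epoch_length``
ending at times ``t_i = epoch_length + i * epoch_step``.  Each epoch is mapped by
a complex Morlet continuous wavelet transform onto a frequency grid, the
log-modulus of the coefficients is taken, and the temporal axis is decimated by
block averaging, yielding one (frequency x time-lag x channel) cube per epoch.
Stacking the cubes over epochs gives a 4th-order feature tensor; the paired
response matrix holds the trajectory sampled at the epoch end times.

The mother wavelet is the complex Morlet

    psi(t) = (pi * B)^(-1/2) * exp(-t^2 / B) * exp(2j * pi * C * t)

with bandwidth parameter ``B`` and centre frequency ``C`` (PyWavelets
``cmorB-C`` convention).  A coefficient at analysis frequency ``f`` uses scale
``a = C * fs / f``.  Epochs are zero-padded at their edges by the convolution;
the block averaging of the decimation step spreads the resulting edge effects
into the first and last lag bins only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pywt

__all__ = [
    "FeatureConfig",
    "EpochFeatureTensor",
    "TrajectoryMatrix",
    "morlet_epoch_features",
    "decimate_temporal",
    "build_epoch_tensor",
]

_DEFAULT_FREQS = tuple(float(f) for f in range(10, 151, 10))


@dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the epoch/CWT feature pipeline.

    Parameters
    ----------
    epoch_length : float
        Epoch duration in seconds (the analysis window ending at the
        prediction time).
    epoch_step : float
        Shift between consecutive epoch end times, seconds.  This is also the
        decoder's decision period.
    freq_grid : sequence of float
        Analysis frequencies in Hz, strictly increasing, all below Nyquist.
    n_time_bins : int
        Number of temporal lag bins after decimation; must divide the epoch
        sample count.
    sampling_rate : float
        Recording sampling rate, Hz.
    log_floor : float
        Positive floor applied to the CWT modulus before the logarithm so the
        all-zero epoch is well defined.
    morlet_bandwidth, morlet_center : float
        ``B`` and ``C`` of the ``cmorB-C`` mother wavelet.  The default
        ``B=2, C=1`` makes adjacent 10 Hz bins resolvable over a 1 s epoch.
    artifact_filter : callable, optional
        Hook ``recording -> recording`` applied to the raw multichannel array
        before epoching (e.g. an artifact-removal stage); default identity.
    """

    epoch_length: float = 1.0
    epoch_step: float = 0.1
    freq_grid: Sequence[float] = _DEFAULT_FREQS
    n_time_bins: int = 10
    sampling_rate: float = 1000.0
    log_floor: float = 1e-12
    morlet_bandwidth: float = 2.0
    morlet_center: float = 1.0
    artifact_filter: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.epoch_length <= 0 or self.epoch_step <= 0:
            raise ValueError("epoch_length and epoch_step must be positive")
        freqs = np.asarray(self.freq_grid, dtype=float)
        if freqs.ndim != 1 or len(freqs) == 0:
            raise ValueError("freq_grid must be a non-empty 1-D sequence")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("freq_grid must be strictly increasing")
        if freqs[-1] >= self.sampling_rate / 2:
            raise ValueError("all analysis frequencies must lie below Nyquist")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be positive")
        if self.n_time_bins < 1:
            raise ValueError("n_time_bins must be >= 1")
        if self.epoch_samples % self.n_time_bins != 0:
            raise ValueError(
                f"n_time_bins={self.n_time_bins} must divide the epoch sample "
                f"count {self.epoch_samples}"
            )

    @property
    def epoch_samples(self) -> int:
        return int(round(self.epoch_length * self.sampling_rate))

    @property
    def wavelet_name(self) -> str:
        return f"cmor{self.morlet_bandwidth}-{self.morlet_center}"

    @property
    def scales(self) -> np.ndarray:
        """CWT scales matching ``freq_grid`` (a = C * fs / f)."""
        freqs = np.asarray(self.freq_grid, dtype=float)
        return self.morlet_center * self.sampling_rate / freqs

    @property
    def lag_times(self) -> np.ndarray:
        """Centres of the decimated lag bins, seconds relative to epoch end."""
        width = self.epoch_length / self.n_time_bins
        return -self.epoch_length + (np.arange(self.n_time_bins) + 0.5) * width


@dataclass
class EpochFeatureTensor:
    """4-way feature block: epochs x frequency x time-lag x channel."""

    values: np.ndarray
    epoch_times: np.ndarray
    freq_hz: np.ndarray
    lag_s: np.ndarray
    channel_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.epoch_times = np.asarray(self.epoch_times, dtype=float)
        self.freq_hz = np.asarray(self.freq_hz, dtype=float)
        self.lag_s = np.asarray(self.lag_s, dtype=float)
        self.channel_ids = np.asarray(self.channel_ids)
        if self.values.ndim != 4:
            raise ValueError("feature tensor must be 4-way")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature tensor contains non-finite values")
        n = self.values.shape[0]
        if self.epoch_times.shape != (n,):
            raise ValueError("epoch_times length must match the epoch count")
        if n > 1:
            steps = np.diff(self.epoch_times)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
                raise ValueError("epoch_times must increase with constant step")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def mode_shape(self) -> tuple:
        return self.values.shape[1:]


@dataclass
class TrajectoryMatrix:
    """Time-stamped response matrix (3 positions, or 9 with derivatives)."""

    values: np.ndarray
    times: np.ndarray
    column_roles: tuple = ("x", "y", "z")

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError("trajectory values and times must have equal length")
        if self.values.shape[1] not in (3, 9):
            raise ValueError("trajectory must have 3 columns (or 9 with derivatives)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def step(self) -> float:
        return float(np.median(np.diff(self.times))) if self.n_samples > 1 else np.nan


def morlet_epoch_features(epoch_signal: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    """Log-modulus Morlet CWT of one epoch.

    Parameters
    ----------
    epoch_signal : ndarray, shape (channels, samples)
        One epoch; ``samples`` must equal ``cfg.epoch_samples``.

    Returns
    -------
    ndarray, shape (len(freq_grid), samples, channels)
        ``log(max(|CWT|, log_floor))`` per frequency, sample and channel.
    """
    sig = np.atleast_2d(np.asarray(epoch_signal, dtype=float))
    if sig.shape[1] != cfg.epoch_samples:
        raise ValueError(
            f"epoch must have {cfg.epoch_samples} samples, got {sig.shape[1]}"
        )
    if not np.all(np.isfinite(sig)):
        raise ValueError("epoch contains non-finite samples")
    coef, _ = pywt.cwt(sig, cfg.scales, cfg.wavelet_name, axis=-1)
    # coef: (freq, channels, samples) -> (freq, samples, channels)
    mod = np.abs(coef).transpose(0, 2, 1)
    return np.log(np.maximum(mod, cfg.log_floor))


def decimate_temporal(cube: np.ndarray, n_bins: int) -> np.ndarray:
    """Block-average the temporal axis of a (freq, samples, channels) cube."""
    cube = np.asarray(cube, dtype=float)
    if cube.ndim != 3:
        raise ValueError("cube must be 3-way (freq, samples, channels)")
    n_freq, n_samp, n_chan = cube.shape
    if n_samp % n_bins != 0:
        raise ValueError(f"{n_samp} samples not divisible into {n_bins} bins")
    block = n_samp // n_bins
    return cube.reshape(n_freq, n_bins, block, n_chan).mean(axis=2)


def _epoch_end_times(total_duration: float, cfg: FeatureConfig) -> np.ndarray:
    # t_i = epoch_length + i * epoch_step; small slack guards float round-off
    n = int(np.floor((total_duration - cfg.epoch_length) / cfg.epoch_step + 1e-9)) + 1
    if n < 1:
        raise ValueError("recording shorter than one epoch")
    return cfg.epoch_length + np.arange(n) * cfg.epoch_step


def build_epoch_tensor(
    recording: np.ndarray,
    trajectory: TrajectoryMatrix,
    cfg: FeatureConfig,
) -> tuple[EpochFeatureTensor, TrajectoryMatrix]:
    """Run the full epoch/CWT/decimation pipeline over a recording.

    ``recording`` is (channels, samples) covering ``[0, T]``; epochs end at
    ``t_i = epoch_length + i*epoch_step`` while ``t_i <= T``.  The response row
    for epoch ``i`` is the trajectory sample nearest in time to ``t_i``
    (causal features: the epoch covers ``[t_i - epoch_length, t_i]``).
    """
    rec = np.atleast_2d(np.asarray(recording, dtype=float))
    if cfg.artifact_filter is not None:
        rec = np.atleast_2d(np.asarray(cfg.artifact_filter(rec), dtype=float))
    n_chan, n_samp = rec.shape
    total = n_samp / cfg.sampling_rate
    ends = _epoch_end_times(total, cfg)
    tol = cfg.epoch_step / 2 + 1e-9
    if trajectory.times[0] > ends[0] + tol or trajectory.times[-1] < ends[-1] - tol:
        raise ValueError("trajectory does not cover the epoch end times")

    epoch_len = cfg.epoch_samples
    n_epochs = len(ends)
    out = np.empty((n_epochs, len(cfg.freq_grid), cfg.n_time_bins, n_chan))
    for i, t_end in enumerate(ends):
        stop = int(round(t_end * cfg.sampling_rate))
        cube = morlet_epoch_features(rec[:, stop - epoch_len : stop], cfg)
        out[i] = decimate_temporal(cube, cfg.n_time_bins)

    idx = np.clip(
        np.searchsorted(trajectory.times, ends), 0, trajectory.n_samples - 1
    )
    lower = np.maximum(idx - 1, 0)
    pick_lower = np.abs(trajectory.times[lower] - ends) <= np.abs(
        trajectory.times[idx] - ends
    )
    nearest = np.where(pick_lower, lower, idx)

    tensor = EpochFeatureTensor(
        values=out,
        epoch_times=ends,
        freq_hz=np.asarray(cfg.freq_grid, dtype=float),
        lag_s=cfg.lag_times,
        channel_ids=np.arange(n_chan),
    )
    resp = TrajectoryMatrix(
        values=trajectory.values[nearest],
        times=ends,
        column_roles=trajectory.column_roles,
    )
    return tensor, resp
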