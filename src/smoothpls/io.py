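"""HDF5/CSV serialization for recordings, tensors, trajectories and models.

Feature tensors and models travel as single HDF5 files with named axis
datasets; trajectories as ``time,x,y,z`` CSV; toy recordings either as HDF5
(``recording`` dataset + ``sampling_rate`` attribute) or one-channel-per-
column CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .features import EpochFeatureTensor, TrajectoryMatrix
from .kalman import KalmanParams
from .npls import NplsModel

SCHEMA_VERSION = 1

__all__ = [
    "save_tensor", "load_tensor", "save_trajectory", "load_trajectory",
    "save_recording", "load_recording", "save_model", "load_model",
]


def save_tensor(path, tensor: EpochFeatureTensor) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("values", data=tensor.values)
        f.create_dataset("epoch_time", data=tensor.epoch_times)
        f.create_dataset("freq_hz", data=tensor.freq_hz)
        f.create_dataset("lag_s", data=tensor.lag_s)
        f.create_dataset("channel", data=np.asarray(tensor.channel_ids))


def load_tensor(path) -> EpochFeatureTensor:
    with h5py.File(path, "r") as f:
        return EpochFeatureTensor(
            values=f["values"][()],
            epoch_times=f["epoch_time"][()],
            freq_hz=f["freq_hz"][()],
            lag_s=f["lag_s"][()],
            channel_ids=f["channel"][()],
        )


def save_trajectory(path, traj: TrajectoryMatrix) -> None:
    header = "time," + ",".join(str(r) for r in traj.column_roles)
    data = np.column_stack([traj.times, traj.values])
    np.savetxt(path, data, delimiter=",", header=header, comments="")


def load_trajectory(path) -> TrajectoryMatrix:
    with open(path) as f:
        roles = tuple(f.readline().strip().split(",")[1:])
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    return TrajectoryMatrix(values=data[:, 1:], times=data[:, 0],
                            column_roles=roles)


def save_recording(path, recording: np.ndarray, sampling_rate: float) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("recording", data=np.atleast_2d(recording))
        d.attrs["sampling_rate"] = sampling_rate


def load_recording(path):
    """Returns (recording, sampling_rate); CSV files carry no rate (None)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        data = np.loadtxt(path, delimiter=",")
        return np.atleast_2d(data).T, None
    with h5py.File(path, "r") as f:
        d = f["recording"]
        return d[()], float(d.attrs["sampling_rate"])


def save_model(path, model, extra_config: dict | None = None) -> None:
    """Serialize an NPLS-family model or Kalman params to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if extra_config is not None:
            f.attrs["config_json"] = json.dumps(extra_config, sort_keys=True)
        if isinstance(model, NplsModel):
            f.attrs["model_type"] = "npls"
            g = f.create_group("npls")
            g.attrs["n_factors"] = model.n_factors
            g.attrs["truncated"] = model.truncated
            for name in ("W1", "W2", "W3", "Q", "T_scores", "U_scores",
                         "x_mean", "y_mean", "B_full"):
                g.create_dataset(name, data=getattr(model, name))
            gb = g.create_group("B_inner")
            for i, b in enumerate(model.B_inner):
                gb.create_dataset(str(i), data=b)
            g.attrs["residual_norms"] = json.dumps(model.residual_norms)
        elif isinstance(model, KalmanParams):
            f.attrs["model_type"] = "kalman"
            g = f.create_group("kalman")
            for name in ("A", "H", "W", "Q", "x_mean", "y_mean", "y0", "P0"):
                g.create_dataset(name, data=getattr(model, name))
        else:
            raise TypeError(f"cannot serialize {type(model).__name__}")


def load_model(path):
    """Returns (model, config_dict)."""
    with h5py.File(path, "r") as f:
        cfg = json.loads(f.attrs.get("config_json", "{}"))
        kind = f.attrs["model_type"]
        if kind == "npls":
            g = f["npls"]
            n = int(g.attrs["n_factors"])
            model = NplsModel(
                n_factors=n,
                W1=g["W1"][()], W2=g["W2"][()], W3=g["W3"][()], Q=g["Q"][()],
                B_inner=[g["B_inner"][str(i)][()] for i in range(n)],
                T_scores=g["T_scores"][()], U_scores=g["U_scores"][()],
                x_mean=g["x_mean"][()], y_mean=g["y_mean"][()],
                B_full=g["B_full"][()],
                residual_norms=json.loads(g.attrs["residual_norms"]),
                truncated=bool(g.attrs["truncated"]),
            )
            return model, cfg
        if kind == "kalman":
            g = f["kalman"]
            model = KalmanParams(
                A=g["A"][()], H=g["H"][()], W=g["W"][()], Q=g["Q"][()],
                x_mean=g["x_mean"][()], y_mean=g["y_mean"][()],
                y0=g["y0"][()], P0=g["P0"][()],
            )
            return model, cfg
        raise ValueError(f"unknown model type {kind!r}")
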