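"""HDF5/CSV persistence for trajectories and multichannel series."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from hiertime.model import ModelParams, InputProtocol, RateTrajectory

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "trajectory_to_csv",
    "save_timeseries",
    "load_timeseries",
]


def save_trajectory(traj: RateTrajectory, path: str | Path) -> Path:
    """Write a RateTrajectory to HDF5 (datasets rE, rI, times; attributes
    dt, seed and JSON-encoded params/protocol snapshots)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("rE", data=traj.rE, compression="gzip")
        f.create_dataset("rI", data=traj.rI, compression="gzip")
        f.create_dataset("times", data=traj.times)
        f.attrs["dt"] = traj.dt
        f.attrs["seed"] = traj.seed
        f.attrs["params"] = json.dumps(dataclasses.asdict(traj.params))
        proto = dataclasses.asdict(traj.protocol)
        proto = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in proto.items()}
        f.attrs["protocol"] = json.dumps(proto)
    return path


def load_trajectory(path: str | Path) -> RateTrajectory:
    with h5py.File(path, "r") as f:
        params = ModelParams(**json.loads(f.attrs["params"]))
        proto_kw = json.loads(f.attrs["protocol"])
        for key in ("baseline_E", "baseline_I"):
            if isinstance(proto_kw.get(key), list):
                proto_kw[key] = np.asarray(proto_kw[key])
        protocol = InputProtocol(**proto_kw)
        return RateTrajectory(
            times=f["times"][:],
            rE=f["rE"][:],
            rI=f["rI"][:],
            dt=float(f.attrs["dt"]),
            params=params,
            protocol=protocol,
            seed=int(f.attrs["seed"]),
        )


def trajectory_to_csv(traj: RateTrajectory, path: str | Path,
                      areas: list[str] | None = None) -> Path:
    """Long-format CSV export (time_ms, area, rE_hz, rI_hz) for small runs."""
    n, t = traj.rE.shape
    names = areas if areas is not None else [f"area{i}" for i in range(n)]
    df = pd.DataFrame({
        "time_ms": np.tile(traj.times, n),
        "area": np.repeat(names, t),
        "rE_hz": traj.rE.ravel(),
        "rI_hz": traj.rI.ravel(),
    })
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def save_timeseries(x: np.ndarray, fs: float, path: str | Path) -> Path:
    """Channels x samples array to HDF5 with an fs (Hz) attribute."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=np.atleast_2d(x), compression="gzip")
        f.attrs["fs"] = fs
    return path


def load_timeseries(path: str | Path) -> tuple[np.ndarray, float]:
    with h5py.File(path, "r") as f:
        return f["data"][:], float(f.attrs["fs"])
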