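"""Reading and writing trajectories, potentials, and profiles.

Trajectories go to HDF5 (groups ``positions``/``velocities`` plus metadata
attributes) or, for small runs, to two-column delimited text.  Potentials
and fitted parameters are JSON with explicit unit fields.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .engine import Trajectory
from .potential import DoubleWellFit

__all__ = ["save_trajectory", "load_trajectory", "fit_to_dict"]


def save_trajectory(traj: Trajectory, path) -> None:
    path = str(path)
    if path.endswith((".txt", ".tsv", ".dat", ".csv")):
        delim = "," if path.endswith(".csv") else " "
        cols = [traj.times, traj.positions]
        header = "time position"
        if traj.velocities is not None:
            cols.append(traj.velocities)
            header += " velocity"
        np.savetxt(path, np.column_stack(cols), delimiter=delim, header=header)
        return
    with h5py.File(path, "w") as fh:
        fh.create_dataset("positions", data=traj.positions)
        if traj.velocities is not None:
            fh.create_dataset("velocities", data=traj.velocities)
        fh.attrs["t0"] = traj.t0
        fh.attrs["dt"] = traj.dt
        fh.attrs["metadata"] = json.dumps(traj.metadata)


def load_trajectory(path) -> Trajectory:
    path = str(path)
    if path.endswith((".txt", ".tsv", ".dat", ".csv")):
        delim = "," if path.endswith(".csv") else None
        data = np.loadtxt(path, comments="#", delimiter=delim)
        t, x = data[:, 0], data[:, 1]
        v = data[:, 2] if data.shape[1] > 2 else None
        dt = float(np.median(np.diff(t)))
        return Trajectory(t0=float(t[0]), dt=dt, positions=x, velocities=v,
                          metadata={"source": path})
    with h5py.File(path, "r") as fh:
        positions = fh["positions"][...]
        velocities = fh["velocities"][...] if "velocities" in fh else None
        meta = json.loads(fh.attrs.get("metadata", "{}"))
        return Trajectory(t0=float(fh.attrs["t0"]), dt=float(fh.attrs["dt"]),
                          positions=positions, velocities=velocities,
                          metadata=meta)


def fit_to_dict(fit: DoubleWellFit) -> dict:
    return {
        "potential": fit.potential.to_dict(),
        "x_shift": fit.x_shift,
        "e_shift": fit.e_shift,
        "residual_norm": fit.residual_norm,
        "minima": list(fit.minima),
        "barrier": fit.barrier,
        "n_points": fit.n_points,
        "units": {"energy": "k_BT", "length": "reaction coordinate"},
    }
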