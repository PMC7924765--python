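"""Persistence: HDF5 containers for trajectories/BOLD, CSV for matrices.

Trajectories and BOLD series go into a hierarchical HDF5 file with the
run parameters stored as attributes; FC matrices and partitions export as
dense CSV or edge lists for downstream tools.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .functional_connectivity import FCMatrix
from .hemodynamics import BoldSeries
from .neural_mass import NetworkTrajectory

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "save_bold",
    "load_bold",
    "export_fc_csv",
    "export_edge_list",
    "export_partition",
]


def _write_attrs(group, **attrs) -> None:
    group.attrs["neurogain_version"] = __version__
    for k, v in attrs.items():
        if v is None:
            continue
        if hasattr(v, "__dataclass_fields__"):
            for kk, vv in asdict(v).items():
                if vv is not None and np.isscalar(vv):
                    group.attrs[f"{k}.{kk}"] = vv
        elif np.isscalar(v) or isinstance(v, (list, tuple)):
            group.attrs[k] = v


def save_trajectory(path: str | Path, traj: NetworkTrajectory, **params) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("trajectory")
        g.create_dataset("time", data=traj.time)
        g.create_dataset("eeg", data=traj.eeg)
        g.create_dataset("rates", data=traj.rates)
        _write_attrs(g, fs=traj.fs, seed=traj.seed, **params)


def load_trajectory(path: str | Path) -> NetworkTrajectory:
    with h5py.File(path, "r") as f:
        g = f["trajectory"]
        return NetworkTrajectory(
            time=g["time"][:],
            eeg=g["eeg"][:],
            rates=g["rates"][:],
            fs=float(g.attrs["fs"]),
            seed=int(g.attrs["seed"]) if "seed" in g.attrs else None,
        )


def save_bold(path: str | Path, bold: BoldSeries, **params) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("bold")
        g.create_dataset("data", data=bold.data)
        _write_attrs(g, fs=bold.fs, filtered=bold.filtered, band=bold.band, **params)


def load_bold(path: str | Path) -> BoldSeries:
    with h5py.File(path, "r") as f:
        g = f["bold"]
        band = tuple(g.attrs["band"]) if "band" in g.attrs else None
        return BoldSeries(
            data=g["data"][:],
            fs=float(g.attrs["fs"]),
            filtered=bool(g.attrs.get("filtered", False)),
            band=band,
        )


def bold_to_csv(path: str | Path, bold: BoldSeries, labels=None) -> None:
    """Time-by-region CSV with region labels as header."""
    cols = labels or [f"region_{i}" for i in range(bold.n_nodes)]
    t = np.arange(bold.data.shape[1]) / bold.fs
    df = pd.DataFrame(bold.data.T, columns=cols)
    df.insert(0, "time_s", t)
    df.to_csv(path, index=False)


def export_fc_csv(path: str | Path, fc: FCMatrix, labels=None) -> None:
    cols = labels or [f"region_{i}" for i in range(fc.n)]
    pd.DataFrame(fc.values, index=cols, columns=cols).to_csv(path)


def export_edge_list(path: str | Path, fc: FCMatrix) -> None:
    """Edges as (i, j, weight, p_raw, p_fdr); thresholded FCs list survivors only."""
    iu = np.triu_indices(fc.n, k=1)
    rows = {
        "i": iu[0],
        "j": iu[1],
        "weight": fc.values[iu],
        "p_raw": fc.p_raw[iu] if fc.p_raw is not None else np.nan,
        "p_fdr": fc.p_fdr[iu] if fc.p_fdr is not None else np.nan,
    }
    df = pd.DataFrame(rows)
    if fc.thresholded and fc.mask is not None:
        df = df[fc.mask[iu]]
    df.to_csv(path, index=False)


def export_partition(path: str | Path, labels_per_node, region_labels=None) -> None:
    region_labels = region_labels or [f"region_{i}" for i in range(len(labels_per_node))]
    pd.DataFrame({"node": region_labels, "module": labels_per_node}).to_csv(path, index=False)
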