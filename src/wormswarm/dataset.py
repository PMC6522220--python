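"""Trajectory container and HDF5 / CSV readers-writers.

The on-disk HDF5 schema is::

    /frames                       (F,) frame times, s
    /worms/<id>/centroid          (F, 2) head-region centroid, mm (NaN = missing)
    /worms/<id>/skeleton          (F, M, 2) optional full skeleton, mm
    /food/t_<k>                   optional food-grid snapshots
    /food_times                   (K,) times of the food snapshots
    attrs: arena_side, dt, record_every, seed, params (JSON), provenance,
           frame_rate, food_cell

The flat CSV export has columns ``frame, worm, x, y``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["TrajectoryDataset", "read_trajectory", "write_trajectory", "interpolate_missing"]


@dataclass
class TrajectoryDataset:
    """Per-frame, per-worm positions with arena metadata.

    Attributes
    ----------
    times : (F,) array
        Frame times in seconds, strictly increasing.
    centroids : (F, N, 2) array
        Head-region centroid per worm per frame, mm.  NaN marks missing.
    skeletons : (F, N, M, 2) array or None
        Optional full body skeletons, mm.
    arena_side : float or None
        Side of the periodic square arena; ``None`` for bounded
        (experimental-style) data, in which case distances are plain
        Euclidean.
    provenance : str
        One of ``simulated``, ``fixture``, ``imported``.
    """

    times: np.ndarray
    centroids: np.ndarray
    skeletons: np.ndarray | None = None
    arena_side: float | None = None
    provenance: str = "imported"
    seed: int | None = None
    params: dict[str, Any] | None = None
    food_times: np.ndarray | None = None
    food_snapshots: np.ndarray | None = None   # (K, n, n)
    food_cell: float | None = None
    truth: dict[str, Any] | None = None        # fixture ground truth (not serialised)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.times.ndim != 1 or self.centroids.ndim != 3 or self.centroids.shape[2] != 2:
            raise ValueError("times must be (F,), centroids (F, N, 2)")
        if self.centroids.shape[0] != self.times.shape[0]:
            raise ValueError("times and centroids disagree on frame count")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    @property
    def n_worms(self) -> int:
        return self.centroids.shape[1]

    @property
    def frame_rate(self) -> float:
        """Sampling rate, Hz (median frame interval)."""
        if self.times.size < 2:
            return float("nan")
        return 1.0 / float(np.median(np.diff(self.times)))

    def frames(self, drop_missing: bool = True) -> list[np.ndarray]:
        """Per-frame (n_i, 2) position arrays (missing worms dropped)."""
        out = []
        for f in range(self.n_frames):
            pts = self.centroids[f]
            if drop_missing:
                pts = pts[np.isfinite(pts).all(axis=1)]
            out.append(pts)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        F, N, _ = self.centroids.shape
        frame = np.repeat(np.arange(F), N)
        worm = np.tile(np.arange(N), F)
        xy = self.centroids.reshape(F * N, 2)
        return pd.DataFrame({"frame": frame, "worm": worm, "x": xy[:, 0], "y": xy[:, 1]})


def interpolate_missing(ds: TrajectoryDataset) -> TrajectoryDataset:
    """Linearly interpolate NaN centroid gaps per worm (interior gaps only)."""
    cent = ds.centroids.copy()
    t = ds.times
    for w in range(ds.n_worms):
        for ax in range(2):
            y = cent[:, w, ax]
            ok = np.isfinite(y)
            if 0 < ok.sum() < y.size:
                first, last = np.argmax(ok), len(ok) - 1 - np.argmax(ok[::-1])
                gap = ~ok & (np.arange(len(ok)) >= first) & (np.arange(len(ok)) <= last)
                y[gap] = np.interp(t[gap], t[ok], y[ok])
    out = TrajectoryDataset(
        times=t, centroids=cent, skeletons=ds.skeletons, arena_side=ds.arena_side,
        provenance=ds.provenance, seed=ds.seed, params=ds.params,
        food_times=ds.food_times, food_snapshots=ds.food_snapshots,
        food_cell=ds.food_cell, truth=ds.truth,
    )
    return out


# ---------------------------------------------------------------------------
# HDF5
# ---------------------------------------------------------------------------

def _write_hdf5(path: Path, ds: TrajectoryDataset) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("frames", data=ds.times)
        g = fh.create_group("worms")
        for w in range(ds.n_worms):
            gw = g.create_group(str(w))
            gw.create_dataset("centroid", data=ds.centroids[:, w])
            if ds.skeletons is not None:
                gw.create_dataset("skeleton", data=ds.skeletons[:, w])
        if ds.food_snapshots is not None:
            gf = fh.create_group("food")
            for k in range(ds.food_snapshots.shape[0]):
                gf.create_dataset(f"t_{k}", data=ds.food_snapshots[k])
            fh.create_dataset("food_times", data=ds.food_times)
            if ds.food_cell is not None:
                fh.attrs["food_cell"] = ds.food_cell
        if ds.arena_side is not None:
            fh.attrs["arena_side"] = ds.arena_side
        if ds.seed is not None:
            fh.attrs["seed"] = ds.seed
        if ds.params is not None:
            fh.attrs["params"] = json.dumps(ds.params)
            fh.attrs["dt"] = ds.params.get("dt", float("nan"))
        if ds.times.size > 1:
            fh.attrs["record_every"] = float(np.median(np.diff(ds.times)))
        fh.attrs["provenance"] = ds.provenance


def _read_hdf5(path: Path) -> TrajectoryDataset:
    import h5py

    with h5py.File(path, "r") as fh:
        for req in ("frames", "worms"):
            if req not in fh:
                raise ValueError(f"{path}: missing required dataset/group '/{req}'")
        times = fh["frames"][:]
        ids = sorted(fh["worms"].keys(), key=int)
        cents = np.stack([fh["worms"][i]["centroid"][:] for i in ids], axis=1)
        skel = None
        if ids and "skeleton" in fh["worms"][ids[0]]:
            skel = np.stack([fh["worms"][i]["skeleton"][:] for i in ids], axis=1)
        food_times = food_snaps = None
        if "food" in fh:
            food_times = fh["food_times"][:]
            food_snaps = np.stack(
                [fh["food"][f"t_{k}"][:] for k in range(len(food_times))], axis=0
            )
        params = json.loads(fh.attrs["params"]) if "params" in fh.attrs else None
        return TrajectoryDataset(
            times=times,
            centroids=cents,
            skeletons=skel,
            arena_side=float(fh.attrs["arena_side"]) if "arena_side" in fh.attrs else None,
            provenance=str(fh.attrs.get("provenance", "imported")),
            seed=int(fh.attrs["seed"]) if "seed" in fh.attrs else None,
            params=params,
            food_times=food_times,
            food_snapshots=food_snaps,
            food_cell=float(fh.attrs["food_cell"]) if "food_cell" in fh.attrs else None,
        )


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _write_csv(path: Path, ds: TrajectoryDataset) -> None:
    ds.to_dataframe().to_csv(path, index=False)


def _read_csv(path: Path, frame_rate: float = 1.0, arena_side: float | None = None) -> TrajectoryDataset:
    df = pd.read_csv(path)
    required = {"frame", "worm", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: CSV missing required column(s) {sorted(missing)}")
    frames = np.sort(df["frame"].unique())
    worms = np.sort(df["worm"].unique())
    fidx = {f: i for i, f in enumerate(frames)}
    widx = {w: i for i, w in enumerate(worms)}
    cents = np.full((len(frames), len(worms), 2), np.nan)
    cents[df["frame"].map(fidx), df["worm"].map(widx)] = df[["x", "y"]].to_numpy()
    times = frames.astype(float) / frame_rate
    return TrajectoryDataset(times=times, centroids=cents, arena_side=arena_side)


def write_trajectory(path: str | Path, ds: TrajectoryDataset) -> None:
    """Write a dataset to ``.h5``/``.hdf5`` or ``.csv`` (by extension)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_hdf5(path, ds)
    elif path.suffix == ".csv":
        _write_csv(path, ds)
    else:
        raise ValueError(f"unsupported trajectory format: {path.suffix}")


def read_trajectory(
    path: str | Path,
    interpolate: bool = False,
    frame_rate: float = 1.0,
    arena_side: float | None = None,
) -> TrajectoryDataset:
    """Read a trajectory file; optionally interpolate missing frames."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        ds = _read_hdf5(path)
    elif path.suffix == ".csv":
        ds = _read_csv(path, frame_rate=frame_rate, arena_side=arena_side)
    else:
        raise ValueError(f"unsupported trajectory format: {path.suffix}")
    return interpolate_missing(ds) if interpolate else ds
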