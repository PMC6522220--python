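"""Seeded synthetic trajectory fixtures with known ground truth.

Each generator emulates one statistical feature of multi-worm tracking
output (40 worms, ~9 Hz, mm coordinates) and records its ground truth in
``dataset.truth`` so analyses can be tested against construction:

* ``uniform`` — spatially uniform independent positions per frame;
* ``clustered`` — Gaussian clusters plus a uniform background;
* ``scripted_reversal`` — a single track with scripted backward
  excursions of known lengths;
* ``rigid_blob`` — a rigidly translating group of worms;
* ``two_state_speed`` — slow worms packed densely, fast worms dispersed.
"""
from __future__ import annotations

from typing import Any

import numpy as np

from .dataset import TrajectoryDataset

__all__ = ["generate_fixtures", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("uniform", "clustered", "scripted_reversal", "rigid_blob", "two_state_speed")


def _uniform(rng: np.random.Generator, p: dict[str, Any]) -> TrajectoryDataset:
    n_frames = p.get("n_frames", 20)
    n_worms = p.get("n_worms", 40)
    side = p.get("arena_side", 8.0)
    dt = p.get("frame_dt", 30.0)
    cents = rng.uniform(0, side, size=(n_frames, n_worms, 2))
    return TrajectoryDataset(
        times=np.arange(1, n_frames + 1) * dt,
        centroids=cents,
        arena_side=side,
        provenance="fixture",
        truth={"kind": "uniform"},
    )


def _clustered(rng: np.random.Generator, p: dict[str, Any]) -> TrajectoryDataset:
    n_frames = p.get("n_frames", 20)
    n_worms = p.get("n_worms", 40)
    side = p.get("arena_side", 8.0)
    dt = p.get("frame_dt", 30.0)
    n_clusters = p.get("n_clusters", 2)
    sigma = p.get("cluster_sigma", 0.2)
    background = p.get("background_fraction", 0.1)
    cents = np.empty((n_frames, n_worms, 2))
    centers = rng.uniform(side * 0.2, side * 0.8, size=(n_clusters, 2))
    for f in range(n_frames):
        which = rng.integers(0, n_clusters, size=n_worms)
        pts = centers[which] + rng.normal(0, sigma, size=(n_worms, 2))
        bg = rng.uniform(size=n_worms) < background
        pts[bg] = rng.uniform(0, side, size=(int(bg.sum()), 2))
        cents[f] = np.mod(pts, side)
    return TrajectoryDataset(
        times=np.arange(1, n_frames + 1) * dt,
        centroids=cents,
        arena_side=side,
        provenance="fixture",
        truth={"kind": "clustered", "sigma": sigma, "centers": centers},
    )


def _scripted_reversal(rng: np.random.Generator, p: dict[str, Any]) -> TrajectoryDataset:
    """One worm crawling along +x with scripted backward excursions.

    ``lengths_um`` lists the backward path length of each excursion;
    the detectable ground truth counts those of at least 50 µm.
    """
    fps = p.get("frame_rate", 9.0)
    # 20 um per frame at 9 Hz, so scripted lengths quantise cleanly
    speed_um = p.get("speed_um_per_s", 180.0)
    lengths = p.get("lengths_um", [100.0, 60.0, 55.0])
    fwd_s = p.get("forward_s", 10.0)
    step = speed_um / fps / 1000.0  # mm per frame
    xs = [0.0]
    events = []
    for L_um in list(lengths) + [None]:
        for _ in range(int(round(fwd_s * fps))):
            xs.append(xs[-1] + step)
        if L_um is None:
            break
        n_back = max(1, int(round(L_um / 1000.0 / step)))
        start = len(xs)
        for _ in range(n_back):
            xs.append(xs[-1] - step)
        events.append((start, len(xs), n_back * step * 1000.0))
    x = np.asarray(xs)
    cents = np.zeros((x.size, 1, 2))
    cents[:, 0, 0] = x
    skel = np.tile(np.array([1.0, 0.0]), (x.size, 1))  # pharynx points along +x
    truth = {
        "kind": "scripted_reversal",
        "events": events,
        # ground truth from the lengths actually constructed (quantised to
        # whole frames), with a half-step margin against float ties
        "n_detectable": int(sum(1 for *_, L in events if L >= 50.0 - 1e-9)),
        "skeleton_vec": skel,
        "frame_rate": fps,
    }
    return TrajectoryDataset(
        times=np.arange(1, x.size + 1) / fps,
        centroids=cents,
        provenance="fixture",
        truth=truth,
    )


def _rigid_blob(rng: np.random.Generator, p: dict[str, Any]) -> TrajectoryDataset:
    """A disc of worms translating rigidly at a known speed."""
    side = p.get("arena_side", 8.0)
    n_worms = p.get("n_worms", 20)
    n_frames = p.get("n_frames", 60)
    dt = p.get("frame_dt", 30.0)
    speed_um_min = p.get("speed_um_per_min", 150.0)
    radius = p.get("blob_radius", 0.5)
    theta = rng.uniform(0, 2 * np.pi, n_worms)
    r = radius * np.sqrt(rng.uniform(size=n_worms))
    offsets = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    direction = np.array([1.0, 0.3])
    direction /= np.linalg.norm(direction)
    v_mm_s = speed_um_min / 1000.0 / 60.0
    start = np.array([side * 0.25, side * 0.25])
    cents = np.empty((n_frames, n_worms, 2))
    for f in range(n_frames):
        center = start + direction * v_mm_s * f * dt
        cents[f] = np.mod(center + offsets, side)
    return TrajectoryDataset(
        times=np.arange(1, n_frames + 1) * dt,
        centroids=cents,
        arena_side=side,
        provenance="fixture",
        truth={"kind": "rigid_blob", "speed_um_per_min": speed_um_min},
    )


def _two_state_speed(rng: np.random.Generator, p: dict[str, Any]) -> TrajectoryDataset:
    """Slow worms in a dense patch, fast worms spread out (9 Hz tracks)."""
    side = p.get("arena_side", 8.0)
    n_each = p.get("n_each", 20)
    n_frames = p.get("n_frames", 200)
    fps = p.get("frame_rate", 9.0)
    v_slow = p.get("v_slow", 0.035)
    v_fast = p.get("v_fast", 0.35)
    n = 2 * n_each
    pos = np.empty((n, 2))
    pos[:n_each] = np.array([side / 4, side / 4]) + rng.normal(0, 0.15, (n_each, 2))
    pos[n_each:] = rng.uniform(0, side, (n_each, 2))
    speeds = np.r_[np.full(n_each, v_slow), np.full(n_each, v_fast)]
    ang = rng.uniform(0, 2 * np.pi, n)
    cents = np.empty((n_frames, n, 2))
    for f in range(n_frames):
        ang += rng.normal(0, 0.05, n)
        # slow worms stay in the patch: reflect their random walk towards it
        pos += np.column_stack([np.cos(ang), np.sin(ang)]) * speeds[:, None] / fps
        drift = np.array([side / 4, side / 4]) - pos[:n_each]
        pos[:n_each] += 0.02 * drift
        pos = np.mod(pos, side)
        cents[f] = pos
    return TrajectoryDataset(
        times=np.arange(1, n_frames + 1) / fps,
        centroids=cents,
        arena_side=side,
        provenance="fixture",
        truth={"kind": "two_state_speed", "v_slow": v_slow, "v_fast": v_fast, "n_each": n_each},
    )


_GENERATORS = {
    "uniform": _uniform,
    "clustered": _clustered,
    "scripted_reversal": _scripted_reversal,
    "rigid_blob": _rigid_blob,
    "two_state_speed": _two_state_speed,
}


def generate_fixtures(kind: str, params: dict[str, Any] | None = None, seed: int = 0) -> TrajectoryDataset:
    """Generate a deterministic synthetic dataset of the given kind.

    ``dataset.truth`` holds the construction ground truth (event counts,
    blob speed, cluster geometry, ...) for use as a test oracle.
    """
    if kind not in _GENERATORS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    rng = np.random.default_rng(seed)
    ds = _GENERATORS[kind](rng, params or {})
    ds.seed = seed
    return ds
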