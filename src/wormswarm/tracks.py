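"""Individual- and cluster-level analyses of trajectory data.

Implements the signed-speed / reversal-detection pipeline used on
pharynx-tracked worms, density-binned reversal rates with a subsampling
bootstrap, density-binned speed histograms, and blob-based cluster
tracking with smoothed centroid speeds.

Positions enter in mm; reversal path lengths are reported in µm and
cluster speeds in µm/min, matching the conventions of multi-worm
tracking outputs.  Pixel-based thresholds use a µm-per-pixel
calibration (default 10 µm/px, the fixture convention).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._kernels import min_image
from .dataset import TrajectoryDataset

__all__ = [
    "ReversalEvent",
    "ClusterTrack",
    "signed_speed",
    "detect_reversals",
    "reversal_rate_by_density",
    "speed_profiles_by_density",
    "cluster_tracks",
]


# ---------------------------------------------------------------------------
# Signed speed and reversals
# ---------------------------------------------------------------------------

@dataclass
class ReversalEvent:
    """One backward excursion of a worm."""

    worm: int
    start_frame: int
    end_frame: int
    path_length_um: float
    pre_disp_px_per_frame: float
    post_disp_px_per_frame: float


def _interp_nan(y: np.ndarray) -> np.ndarray:
    out = y.copy()
    ok = np.isfinite(out)
    if 0 < ok.sum() < out.size:
        idx = np.arange(out.size)
        first, last = np.argmax(ok), out.size - 1 - np.argmax(ok[::-1])
        gap = ~ok & (idx >= first) & (idx <= last)
        out[gap] = np.interp(idx[gap], idx[ok], out[ok])
    return out


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    return ndimage.uniform_filter1d(y, size=window, mode="nearest")


def signed_speed(
    centroids_mm: np.ndarray,
    skeleton_vec: np.ndarray,
    frame_rate: float,
    interpolate: bool = True,
    smooth_s: float = 0.5,
) -> np.ndarray:
    """Signed centroid speed, µm/s, one value per frame.

    The sign is that of the dot product between the skeleton (pharynx)
    vector and the velocity vector — positive for forward motion; the
    magnitude is the centroid speed.  Missing frames are linearly
    interpolated and the series is smoothed with a moving average over
    ``smooth_s`` seconds (default half a second).
    """
    c = np.asarray(centroids_mm, dtype=float).copy()
    if c.size == 0 or not np.isfinite(c).any():
        return np.empty(0)
    if interpolate:
        for ax in range(2):
            c[:, ax] = _interp_nan(c[:, ax])
    v = np.gradient(c, axis=0) * frame_rate          # mm/s
    sk = np.asarray(skeleton_vec, dtype=float)
    sign = np.sign(np.einsum("ij,ij->i", sk, v))
    sign[sign == 0] = 1.0
    speed = np.hypot(v[:, 0], v[:, 1]) * 1000.0       # µm/s
    out = sign * speed
    window = max(1, int(round(smooth_s * frame_rate)))
    return _moving_average(out, window)


def detect_reversals(
    speed_series: np.ndarray,
    positions_mm: np.ndarray,
    frame_rate: float,
    worm: int = 0,
    um_per_px: float = 10.0,
    min_length_um: float = 50.0,
    min_disp_px_per_frame: float = 0.5,
    disp_window_s: float = 0.5,
) -> list[ReversalEvent]:
    """Detect reversal events from a signed-speed series.

    An event is a maximal run of negative signed speed that starts at a
    positive-to-negative sign change.  Events are kept only if the
    backward path length is at least ``min_length_um`` and the mean
    centroid displacement in the ``disp_window_s`` windows before and
    after the event is at least ``min_disp_px_per_frame`` pixels/frame.
    """
    if um_per_px is None or um_per_px <= 0:
        raise ValueError("a positive µm/pixel calibration is required")
    s = np.asarray(speed_series, dtype=float)
    pos = np.asarray(positions_mm, dtype=float)
    if s.size == 0:
        return []
    step_um = np.hypot(*np.diff(pos, axis=0).T) * 1000.0  # per-frame displacement
    w = max(1, int(round(disp_window_s * frame_rate)))
    events: list[ReversalEvent] = []
    f = 1
    while f < s.size:
        if s[f] < 0 and s[f - 1] >= 0:
            start = f
            end = start
            while end < s.size and s[end] < 0:
                end += 1
            path = step_um[start - 1:end - 1].sum()
            pre = step_um[max(0, start - 1 - w):start - 1]
            post = step_um[end - 1:end - 1 + w]
            pre_d = pre.mean() / um_per_px if pre.size else 0.0
            post_d = post.mean() / um_per_px if post.size else 0.0
            if (
                path >= min_length_um
                and pre_d >= min_disp_px_per_frame
                and post_d >= min_disp_px_per_frame
            ):
                events.append(
                    ReversalEvent(worm, start, end, float(path), float(pre_d), float(post_d))
                )
            f = end
        else:
            f += 1
    return events


# ---------------------------------------------------------------------------
# Density-binned reversal rates
# ---------------------------------------------------------------------------

def reversal_rate_by_density(
    densities: np.ndarray,
    forward: np.ndarray,
    event_frames: np.ndarray,
    frame_dt: float,
    bins: np.ndarray,
    n_boot: int = 100,
    rng: np.random.Generator | int | None = 0,
    relative: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reversal rate per local-density bin, with a subsampling bootstrap.

    Parameters
    ----------
    densities : (K,) array
        Local k-NN density of every worm-frame.
    forward : (K,) bool array
        Worm-frames spent in forward motion.
    event_frames : (E,) int array
        Worm-frame index at which each reversal event starts.
    frame_dt : float
        Duration of one worm-frame, s.
    bins : array
        Density bin edges, mm^-2.
    relative : bool
        Normalise rates to the lowest occupied density bin.

    Returns
    -------
    rates, boot_mean, boot_std : per-bin arrays (NaN where a bin has no
    forward time).  The bootstrap resamples worm-frames with
    replacement ``n_boot`` times (default 100).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    densities = np.asarray(densities, dtype=float)
    forward = np.asarray(forward, dtype=bool)
    event_frames = np.asarray(event_frames, dtype=np.intp)
    edges = np.asarray(bins, dtype=float)
    nb = len(edges) - 1
    K = densities.size
    which = np.clip(np.digitize(densities, edges) - 1, -1, nb)
    ev_count = np.zeros(K)
    np.add.at(ev_count, event_frames, 1.0)

    def _rates(idx: np.ndarray) -> np.ndarray:
        out = np.full(nb, np.nan)
        b = which[idx]
        fwd = forward[idx]
        ev = ev_count[idx]
        for k in range(nb):
            sel = b == k
            ft = fwd[sel].sum() * frame_dt
            out[k] = ev[sel].sum() / ft if ft > 0 else np.nan
        return out

    base = np.arange(K)
    rates = _rates(base)
    boots = np.stack([_rates(rng.integers(0, K, size=K)) for _ in range(n_boot)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        boot_mean = np.nanmean(boots, axis=0)
        boot_std = np.nanstd(boots, axis=0)
    if relative:
        occupied = np.where(np.isfinite(rates) & (rates > 0))[0]
        if occupied.size:
            ref = rates[occupied[0]]
            rates, boot_mean, boot_std = rates / ref, boot_mean / ref, boot_std / ref
    return rates, boot_mean, boot_std


def speed_profiles_by_density(
    speeds: np.ndarray,
    densities: np.ndarray,
    density_bins: np.ndarray,
    speed_bins: np.ndarray,
) -> np.ndarray:
    """Normalised histogram of absolute speeds for each density bin.

    Returns an (n_density_bins, n_speed_bins) array whose occupied rows
    each sum to one; empty density bins are NaN-masked.
    """
    speeds = np.abs(np.asarray(speeds, dtype=float))
    densities = np.asarray(densities, dtype=float)
    dbins = np.asarray(density_bins, dtype=float)
    sbins = np.asarray(speed_bins, dtype=float)
    H, _, _ = np.histogram2d(densities, speeds, bins=[dbins, sbins])
    tot = H.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        return np.where(tot > 0, H / tot, np.nan)


# ---------------------------------------------------------------------------
# Cluster tracking
# ---------------------------------------------------------------------------

@dataclass
class ClusterTrack:
    """One tracked cluster: sampled centroids, areas and smoothed speed."""

    times: np.ndarray            # (T,) s
    centroids: np.ndarray        # (T, 2) mm, unwrapped
    areas: np.ndarray            # (T,) mm^2
    speeds_um_per_min: np.ndarray  # (T-1,) smoothed centroid speed


def _periodic_blob_labels(occ: np.ndarray, periodic: bool) -> np.ndarray:
    """8-connected blob labels, merged across periodic boundaries."""
    structure = np.ones((3, 3), dtype=int)
    labels, n = ndimage.label(occ, structure=structure)
    if not periodic or n < 2:
        return labels
    # union-find over labels touching across opposite edges (8-connected)
    parent = np.arange(n + 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    n0, n1 = occ.shape
    for i in range(n0):
        if labels[i, 0]:
            for di in (-1, 0, 1):
                j = (i + di) % n0
                if labels[j, n1 - 1]:
                    union(labels[i, 0], labels[j, n1 - 1])
    for j in range(n1):
        if labels[0, j]:
            for dj in (-1, 0, 1):
                i = (j + dj) % n1
                if labels[n0 - 1, i]:
                    union(labels[0, j], labels[n0 - 1, i])
    flat = np.array([find(x) for x in range(n + 1)])
    return flat[labels]


def _blob_centroid(cells_ij: np.ndarray, cell: float, side: float | None) -> np.ndarray:
    """Centroid of blob cell centres; circular mean on a periodic arena."""
    xy = (cells_ij + 0.5) * cell
    if side is None:
        return xy.mean(axis=0)
    ang = 2.0 * np.pi * xy / side
    mean_ang = np.arctan2(np.sin(ang).mean(axis=0), np.cos(ang).mean(axis=0))
    return np.mod(mean_ang / (2.0 * np.pi) * side, side)


def cluster_tracks(
    dataset: TrajectoryDataset,
    sample_every: float = 30.0,
    raster_cell: float = 0.1,
    area_threshold: float | None = None,
    smooth_window: float = 600.0,
    link_dist: float = 1.0,
) -> list[ClusterTrack]:
    """Track worm clusters as super-threshold blobs of rasterised positions.

    Per sampled frame (every ``sample_every`` s) all available worm
    nodes (skeletons if recorded, else centroids) are rasterised onto an
    occupancy grid of ``raster_cell`` mm; 8-connected blobs with area of
    at least ``area_threshold`` mm^2 (default: the raster footprint of 3
    worms) are kept and linked across frames by nearest centroid within
    ``link_dist`` mm.  Centroid positions of each track are smoothed
    with a moving average over ``smooth_window`` s (default 10 min)
    before differencing, giving speeds in µm/min.
    """
    if dataset.times[-1] - dataset.times[0] < smooth_window:
        raise ValueError("dataset shorter than the smoothing window")
    side = dataset.arena_side
    periodic = side is not None
    t = dataset.times
    stride = max(1, int(round(sample_every / np.median(np.diff(t)))))
    sampled = np.arange(0, len(t), stride)

    if dataset.skeletons is not None:
        def frame_points(f: int) -> np.ndarray:
            return dataset.skeletons[f].reshape(-1, 2)
    else:
        def frame_points(f: int) -> np.ndarray:
            return dataset.centroids[f]

    if side is not None:
        extent = side
        origin = 0.0
    else:
        allpts = dataset.centroids[np.isfinite(dataset.centroids).all(axis=2)]
        origin = float(allpts.min()) - raster_cell
        extent = float(allpts.max()) - origin + 2 * raster_cell
    ngrid = max(1, int(np.ceil(extent / raster_cell)))

    # default area threshold: 3 worms' raster footprint, estimated from the
    # first sampled frame (uniformly spread worms ~ disjoint footprints)
    first_pts = frame_points(sampled[0])
    first_pts = first_pts[np.isfinite(first_pts).all(axis=1)]
    n_worms = dataset.n_worms
    if area_threshold is None:
        ij = np.floor((first_pts - origin) / raster_cell).astype(np.intp) % ngrid
        per_worm = len(np.unique(ij[:, 0] * ngrid + ij[:, 1])) / max(1, n_worms)
        area_threshold = 3.0 * per_worm * raster_cell**2

    # ---- per-frame blobs --------------------------------------------------
    frames_blobs: list[list[tuple[np.ndarray, float]]] = []
    for f in sampled:
        pts = frame_points(f)
        pts = pts[np.isfinite(pts).all(axis=1)]
        occ = np.zeros((ngrid, ngrid), dtype=bool)
        ij = np.floor((pts - origin) / raster_cell).astype(np.intp) % ngrid
        occ[ij[:, 0], ij[:, 1]] = True
        labels = _periodic_blob_labels(occ, periodic)
        blobs = []
        for lab in np.unique(labels[labels > 0]):
            cells = np.argwhere(labels == lab)
            area = cells.shape[0] * raster_cell**2
            if area >= area_threshold:
                blobs.append((_blob_centroid(cells, raster_cell, side) + origin, area))
        frames_blobs.append(blobs)

    # ---- greedy nearest-centroid linking ---------------------------------
    tracks: list[dict] = []
    active: list[dict] = []
    for k, blobs in enumerate(frames_blobs):
        time = t[sampled[k]]
        used = set()
        nxt: list[dict] = []
        for tr in active:
            best, best_d = None, np.inf
            for b, (cen, area) in enumerate(blobs):
                if b in used:
                    continue
                last = np.mod(tr["cent"][-1], side) if periodic else tr["cent"][-1]
                d = cen - last
                if periodic:
                    d = min_image(d, side)
                dist = float(np.hypot(*d))
                if dist < best_d:
                    best, best_d = b, dist
            if best is not None and best_d <= link_dist:
                used.add(best)
                cen, area = blobs[best]
                last = np.mod(tr["cent"][-1], side) if periodic else tr["cent"][-1]
                d = cen - last
                if periodic:
                    d = min_image(d, side)
                tr["cent"].append(tr["cent"][-1] + d)  # unwrapped
                tr["times"].append(time)
                tr["areas"].append(area)
                nxt.append(tr)
            else:
                tracks.append(tr)
        for b, (cen, area) in enumerate(blobs):
            if b not in used:
                nxt.append({"times": [time], "cent": [np.asarray(cen, dtype=float)], "areas": [area]})
        active = nxt
    tracks.extend(active)

    # ---- smoothing and speeds --------------------------------------------
    out: list[ClusterTrack] = []
    w = max(1, int(round(smooth_window / sample_every)))
    for tr in tracks:
        times = np.asarray(tr["times"])
        cent = np.stack(tr["cent"])
        if times[-1] - times[0] < smooth_window:
            continue
        sm = np.column_stack(
            [_moving_average(cent[:, 0], w), _moving_average(cent[:, 1], w)]
        )
        dt_s = np.diff(times)
        disp_mm = np.hypot(*np.diff(sm, axis=0).T)
        speeds = disp_mm * 1000.0 / dt_s * 60.0  # µm/min
        out.append(
            ClusterTrack(
                times=times,
                centroids=sm,
                areas=np.asarray(tr["areas"]),
                speeds_um_per_min=speeds,
            )
        )
    return out
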