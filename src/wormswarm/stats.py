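"""Spatial summary statistics of worm position data.

Four statistics quantify aggregation from per-frame point sets (tracked
pharynx positions or simulated head centroids):

* S1 — pair-correlation function: neighbour counts at distance r
  normalised by the expectation for a uniform distribution of the same
  number of points in the same domain;
* S2 — relative-frequency histogram of single-linkage merge distances
  from agglomerative hierarchical clustering (dendrogram branch lengths);
* S3 — positional standard deviation (per axis, axis-averaged, frame-averaged);
* S4 — positional kurtosis (Pearson convention, Gaussian = 3).

All four are computed from positions only, so simulated data can be
restricted to the same single tracked point per worm as the experiments.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from ._kernels import min_image
from .dataset import TrajectoryDataset

__all__ = [
    "SummaryStatSet",
    "knn_density",
    "pair_correlation",
    "branch_length_distribution",
    "dispersion_and_kurtosis",
    "velocity_neighbor_correlation",
    "summarize_dataset",
    "pairwise_distances",
]


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def pairwise_distances(points: np.ndarray, side: float | None = None) -> np.ndarray:
    """Condensed pairwise distances, minimum-image when ``side`` is given."""
    pts = np.asarray(points, dtype=float)
    if side is None:
        return pdist(pts)
    n = pts.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    diff = min_image(pts[iu] - pts[ju], side)
    return np.hypot(diff[:, 0], diff[:, 1])


def _torus_disc_area(r: np.ndarray, side: float) -> np.ndarray:
    """Area of {x : min-image distance to origin <= r} on a square torus."""
    a = side / 2.0
    r = np.asarray(r, dtype=float)
    out = np.where(r <= a, np.pi * r**2, 0.0)
    mid = (r > a) & (r < a * np.sqrt(2.0))
    if np.any(mid):
        rm = r[mid]
        seg = rm**2 * np.arccos(a / rm) - a * np.sqrt(rm**2 - a**2)
        out[mid] = np.pi * rm**2 - 4.0 * seg
    out[r >= a * np.sqrt(2.0)] = side**2
    return out


@dataclass
class SummaryStatSet:
    """The S1–S4 statistics of one dataset, with shared binning."""

    s1: np.ndarray          # pair-correlation values per bin
    s2: np.ndarray          # branch-length relative frequencies per bin
    s3: float               # positional std, mm
    s4: float               # positional kurtosis
    s1_edges: np.ndarray
    s2_edges: np.ndarray
    n_frames: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "s1": self.s1.tolist(),
                "s2": self.s2.tolist(),
                "s3": self.s3,
                "s4": self.s4,
                "s1_edges": self.s1_edges.tolist(),
                "s2_edges": self.s2_edges.tolist(),
                "n_frames": self.n_frames,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SummaryStatSet":
        d = json.loads(text)
        return cls(
            s1=np.asarray(d["s1"], dtype=float),
            s2=np.asarray(d["s2"], dtype=float),
            s3=float(d["s3"]),
            s4=float(d["s4"]),
            s1_edges=np.asarray(d["s1_edges"], dtype=float),
            s2_edges=np.asarray(d["s2_edges"], dtype=float),
            n_frames=int(d.get("n_frames", 0)),
        )

    def s1_small_r_mean(self, r_max: float = 0.5) -> float:
        """Mean S1 over bins entirely below ``r_max`` (aggregation proxy)."""
        keep = (self.s1_edges[1:] <= r_max) & np.isfinite(self.s1)
        return float(self.s1[keep].mean())


# ---------------------------------------------------------------------------
# k-nearest-neighbour density
# ---------------------------------------------------------------------------

def knn_density(
    points: np.ndarray,
    k: int = 6,
    focal_index: int | None = None,
    side: float | None = None,
) -> np.ndarray | float:
    """k-NN areal density: ``k / (pi * d_k^2)`` with the focal point excluded.

    ``d_k`` is the distance from the focal point to its k-th nearest
    neighbour.  Raises when fewer than ``k + 1`` points are available.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n < k + 1:
        raise ValueError(f"knn_density needs at least {k + 1} points, got {n}")
    if side is None:
        d2 = ((pts[None, :, :] - pts[:, None, :]) ** 2).sum(axis=2)
    else:
        diff = min_image(pts[None, :, :] - pts[:, None, :], side)
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(d2, np.inf)
    dk2 = np.partition(d2, k - 1, axis=1)[:, k - 1]
    rho = k / (np.pi * dk2)
    return float(rho[focal_index]) if focal_index is not None else rho


# ---------------------------------------------------------------------------
# S1: pair correlation
# ---------------------------------------------------------------------------

def pair_correlation(
    frames: Sequence[np.ndarray],
    bin_edges: np.ndarray,
    side: float | None = None,
    domain: tuple[float, float, float, float] | None = None,
    rng: np.random.Generator | int | None = None,
    n_ref: int = 10_000,
) -> np.ndarray:
    """Pair-correlation function S1, averaged over frames.

    Per bin and frame, the observed pair count is divided by the pair
    count expected for the same number of points distributed uniformly
    over the same domain.  For a periodic square (``side``) the
    expectation is analytic; for a bounded rectangle (``domain`` =
    (xmin, xmax, ymin, ymax)) it is estimated once from a seeded
    Monte-Carlo uniform reference of at least ``n_ref`` points.
    """
    edges = np.asarray(bin_edges, dtype=float)
    nb = len(edges) - 1
    if side is not None:
        area_frac = np.diff(_torus_disc_area(edges, side)) / side**2
    else:
        if domain is None:
            raise ValueError("bounded data needs an explicit domain rectangle")
        rng = np.random.default_rng(rng if not isinstance(rng, np.random.Generator) else None) \
            if not isinstance(rng, np.random.Generator) else rng
        xmin, xmax, ymin, ymax = domain
        # pool pair-distance histograms over several uniform realisations
        m, n_real = 700, max(1, int(np.ceil(n_ref / 700)))
        ref_hist = np.zeros(nb)
        ref_pairs = 0
        for _ in range(n_real):
            pts = np.column_stack(
                [rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)]
            )
            d = pdist(pts)
            ref_hist += np.histogram(d, bins=edges)[0]
            ref_pairs += d.size
        area_frac = ref_hist / ref_pairs

    ratios = []
    for pts in frames:
        pts = np.asarray(pts, dtype=float)
        pts = pts[np.isfinite(pts).all(axis=1)]
        n = pts.shape[0]
        if n < 2:
            warnings.warn("pair_correlation: frame with <2 points skipped", stacklevel=2)
            continue
        d = pairwise_distances(pts, side=side)
        if np.any(d == 0.0):
            warnings.warn(
                "pair_correlation: coincident points (zero distances)", stacklevel=2
            )
        obs = np.histogram(d, bins=edges)[0]
        expected = n * (n - 1) / 2.0 * area_frac
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios.append(np.where(expected > 0, obs / expected, np.nan))
    if not ratios:
        raise ValueError("pair_correlation: no usable frames")
    with warnings.catch_warnings():
        # bins beyond the maximum periodic distance are all-NaN by design
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(np.stack(ratios), axis=0)


# ---------------------------------------------------------------------------
# S2: single-linkage branch lengths
# ---------------------------------------------------------------------------

def single_linkage_merge_distances(points: np.ndarray, side: float | None = None) -> np.ndarray:
    """The n-1 merge distances of single-linkage agglomerative clustering."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        return np.empty(0)
    return linkage(pairwise_distances(pts, side=side), method="single")[:, 2]


def branch_length_distribution(
    frames: Sequence[np.ndarray],
    bin_edges: np.ndarray,
    side: float | None = None,
) -> np.ndarray:
    """S2: relative-frequency histogram of pooled merge distances."""
    edges = np.asarray(bin_edges, dtype=float)
    merges = []
    for pts in frames:
        pts = np.asarray(pts, dtype=float)
        pts = pts[np.isfinite(pts).all(axis=1)]
        if pts.shape[0] < 2:
            continue
        merges.append(single_linkage_merge_distances(pts, side=side))
    if not merges:
        raise ValueError("branch_length_distribution: no usable frames")
    pooled = np.concatenate(merges)
    hist = np.histogram(pooled, bins=edges)[0].astype(float)
    total = hist.sum()
    return hist / total if total > 0 else hist


# ---------------------------------------------------------------------------
# S3/S4: dispersion and kurtosis
# ---------------------------------------------------------------------------

def dispersion_and_kurtosis(frames: Sequence[np.ndarray]) -> tuple[float, float]:
    """S3 (positional std, mm) and S4 (Pearson kurtosis), frame-averaged.

    Both are computed per axis and averaged over the two axes, then over
    frames.  A Gaussian gives S4 = 3, a per-axis uniform 9/5.
    """
    stds, kurts = [], []
    for pts in frames:
        pts = np.asarray(pts, dtype=float)
        pts = pts[np.isfinite(pts).all(axis=1)]
        if pts.shape[0] < 2:
            continue
        centred = pts - pts.mean(axis=0)
        m2 = (centred**2).mean(axis=0)
        if np.any(m2 == 0.0):
            warnings.warn("dispersion_and_kurtosis: degenerate frame skipped", stacklevel=2)
            continue
        m4 = (centred**4).mean(axis=0)
        stds.append(np.sqrt(m2).mean())
        kurts.append((m4 / m2**2).mean())
    if not stds:
        raise ValueError("dispersion_and_kurtosis: no usable frames")
    return float(np.mean(stds)), float(np.mean(kurts))


# ---------------------------------------------------------------------------
# Velocity–neighbour correlation
# ---------------------------------------------------------------------------

def velocity_neighbor_correlation(
    dataset: TrajectoryDataset,
    distance_bins: np.ndarray,
) -> np.ndarray:
    """Mean cosine between a worm's velocity and the direction to neighbours.

    Per distance bin, averages ``cos(v_i, u_ij)`` over all worm pairs and
    frames, where ``u_ij`` points from worm i to neighbour j.  Positive
    values would indicate movement towards neighbours at that range;
    both experiments and simulations give values near zero.
    """
    edges = np.asarray(distance_bins, dtype=float)
    if dataset.n_frames < 2:
        raise ValueError("need at least two consecutive frames")
    side = dataset.arena_side
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1)
    c = dataset.centroids
    for f in range(dataset.n_frames - 1):
        dtf = dataset.times[f + 1] - dataset.times[f]
        disp = c[f + 1] - c[f]
        if side is not None:
            disp = min_image(disp, side)
        v = disp / dtf
        here = np.isfinite(c[f]).all(axis=1)
        speed = np.hypot(v[:, 0], v[:, 1])
        moving = here & np.isfinite(v).all(axis=1) & (speed > 0.0)
        mov = np.where(moving)[0]
        nb = np.where(here)[0]
        if mov.size == 0 or nb.size < 2:
            continue
        diff = c[f][nb][None, :, :] - c[f][mov][:, None, :]  # mover i -> neighbour j
        if side is not None:
            diff = min_image(diff, side)
        r = np.hypot(diff[..., 0], diff[..., 1])
        cosang = np.einsum("ik,ijk->ij", v[mov] / speed[mov, None], diff) / np.where(
            r > 0, r, np.inf
        )
        self_pair = mov[:, None] == nb[None, :]
        which = np.digitize(r, edges) - 1
        good = (which >= 0) & (which < len(edges) - 1) & (r > 0) & ~self_pair
        np.add.at(sums, which[good], cosang[good])
        np.add.at(counts, which[good], 1.0)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def summarize_dataset(
    dataset: TrajectoryDataset,
    s1_edges: np.ndarray | None = None,
    s2_edges: np.ndarray | None = None,
    last_fraction: float | None = None,
    sample_every: float | None = 30.0,
    rng: np.random.Generator | int | None = 0,
) -> SummaryStatSet:
    """Compute S1–S4 for a dataset with shared frame sampling.

    Simulated datasets are summarised over the final 10% of the run by
    default (the quasi-steady state); experimental-style datasets over
    all frames.  Frames are subsampled to one every ``sample_every``
    seconds.  Deterministic given the binning and seed.
    """
    if s1_edges is None:
        s1_edges = np.arange(0.0, 8.0 + 1e-9, 0.1)
    if s2_edges is None:
        s2_edges = np.arange(0.0, 8.0 + 1e-9, 0.2)
    if last_fraction is None:
        last_fraction = 0.1 if dataset.provenance == "simulated" else 1.0

    t = dataset.times
    t0 = t[-1] - last_fraction * (t[-1] - t[0]) if len(t) > 1 else t[0]
    keep = np.where(t >= t0 - 1e-9)[0]
    if sample_every is not None and len(keep) > 1:
        stride = max(1, int(round(sample_every / np.median(np.diff(t[keep])))))
        keep = keep[::stride]
    frames = [dataset.centroids[f] for f in keep]

    side = dataset.arena_side
    domain = None
    if side is None:
        allpts = np.concatenate([f[np.isfinite(f).all(axis=1)] for f in frames])
        domain = (
            allpts[:, 0].min(), allpts[:, 0].max(),
            allpts[:, 1].min(), allpts[:, 1].max(),
        )
    s1 = pair_correlation(frames, s1_edges, side=side, domain=domain, rng=rng)
    s2 = branch_length_distribution(frames, s2_edges, side=side)
    s3, s4 = dispersion_and_kurtosis(frames)
    return SummaryStatSet(
        s1=s1, s2=s2, s3=s3, s4=s4,
        s1_edges=np.asarray(s1_edges, dtype=float),
        s2_edges=np.asarray(s2_edges, dtype=float),
        n_frames=len(frames),
    )
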