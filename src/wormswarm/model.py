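"""Agent dynamics: chain-like worms with persistent-random-walk heads.

The model is a phenomenological description of *C. elegans* crawling on a
uniform bacterial lawn.  Each worm is a chain of ``M`` nodes of total
length ``L`` whose leading node performs a persistent random walk; the
remaining nodes follow the body.  Three density-dependent behaviours
couple the worms:

* cluster-edge reversals — a worm whose head (but not tail, or vice
  versa) senses contact reverses with Poisson rate ``r' * rho``;
* speed switching — Poisson switching between a slow and a fast crawl
  with rates ``k_slow = k_s0 + k_s' * rho`` and
  ``k_fast = k_f0 * exp(-k_f' * rho)``;
* taxis — neighbours within one worm length pull the heading with
  weight ``f_t / r``.

Local density ``rho`` is sensed as the k-nearest-neighbour areal density
(k = 6 by default) of all worms' head-region centroids, matching the
estimator used on tracking data.  The arena is a periodic square; worms
may overlap (no volume exclusion).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._kernels import end_contacts, follow_chains, min_image
from .dataset import TrajectoryDataset
from .food import FoodField, deplete_step, local_food
from .params import ModelParams

__all__ = [
    "WormState",
    "SimulationState",
    "initialize_state",
    "taxis_drive",
    "taxis_drive_all",
    "update_heading",
    "advance_body",
    "reversal_update",
    "speed_state_update",
    "switching_rates",
    "reversal_probability",
    "knn_density_periodic",
    "step",
    "run_simulation",
]


# ---------------------------------------------------------------------------
# State containers
# ---------------------------------------------------------------------------

@dataclass
class WormState:
    """Read/write view of one agent (nodes in mm; node 0 is the head)."""

    nodes: np.ndarray           # (M, 2)
    heading: float              # rad, direction of the currently leading end
    motility_fast: bool
    reversing: bool
    reversal_time_left: float   # s


@dataclass
class SimulationState:
    """Array-of-structs state of a whole simulation."""

    time: float
    pos: np.ndarray             # (N, M, 2) unwrapped node positions
    headings: np.ndarray        # (N,)
    fast: np.ndarray            # (N,) bool
    reversing: np.ndarray       # (N,) bool
    rev_time_left: np.ndarray   # (N,)
    food: FoodField | None
    rng: np.random.Generator

    @property
    def n_worms(self) -> int:
        return self.pos.shape[0]

    def worm(self, i: int) -> WormState:
        return WormState(
            nodes=self.pos[i],
            heading=float(self.headings[i]),
            motility_fast=bool(self.fast[i]),
            reversing=bool(self.reversing[i]),
            reversal_time_left=float(self.rev_time_left[i]),
        )

    def head_centroids(self, params: ModelParams, wrapped: bool = True) -> np.ndarray:
        """Head-region centroid (mean of the first ceil(0.1 M) nodes)."""
        c = self.pos[:, : params.n_end_nodes].mean(axis=1)
        return np.mod(c, params.arena_side) if wrapped else c


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------

def initialize_state(
    params: ModelParams,
    rng: np.random.Generator | None = None,
    food_enabled: bool = False,
) -> SimulationState:
    """Place N straight worms at random positions and orientations.

    Deterministic given the generator state.  Draw order: head positions
    (N, 2 uniforms), orientations (N uniforms), motility states
    (N uniforms, fast with the zero-density stationary probability
    ``k_f0 / (k_f0 + k_s0)``).
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    N, M, side = params.N, params.M, params.arena_side
    heads = rng.uniform(0.0, side, size=(N, 2))
    angles = rng.uniform(0.0, 2.0 * np.pi, size=N)
    p_fast = params.k_f0 / (params.k_f0 + params.k_s0) if (params.k_f0 + params.k_s0) > 0 else 1.0
    fast = rng.uniform(size=N) < p_fast
    u = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    offsets = -np.arange(M)[None, :, None] * params.rest_spacing * u[:, None, :]
    pos = heads[:, None, :] + offsets
    food = FoodField.uniform(side, params.food_cell) if food_enabled else None
    return SimulationState(
        time=0.0,
        pos=pos,
        headings=angles.copy(),
        fast=fast,
        reversing=np.zeros(N, dtype=bool),
        rev_time_left=np.zeros(N),
        food=food,
        rng=rng,
    )


# ---------------------------------------------------------------------------
# Taxis
# ---------------------------------------------------------------------------

def taxis_drive(
    head_pos: np.ndarray,
    neighbor_heads: np.ndarray,
    f_t: float,
    cutoff: float,
    side: float | None = None,
    r_min: float = 0.0,
) -> np.ndarray:
    """Attractive drive towards neighbouring worms.

    Returns ``f_t * sum_j u_j / r_j`` over neighbours with
    ``0 < r_j <= cutoff``, where ``u_j`` is the unit vector from
    ``head_pos`` towards neighbour j.  Contributions are cumulative;
    neighbours beyond the cutoff (one worm length by default) contribute
    nothing.  With ``side`` given, displacements use the minimum-image
    convention.  ``r_min`` is a short-range cutoff of the 1/r kernel
    (the simulation loop uses ``params.taxis_softening``): neighbours
    already closer than ``r_min`` exert no further pull, which keeps the
    kernel integrable and lets overlapping clusters equilibrate at a
    finite size instead of collapsing to a point.
    """
    head_pos = np.asarray(head_pos, dtype=float)
    nb = np.atleast_2d(np.asarray(neighbor_heads, dtype=float))
    if nb.size == 0 or f_t == 0.0:
        return np.zeros(2)
    diff = nb - head_pos[None, :]
    if side is not None:
        diff = min_image(diff, side)
    r = np.hypot(diff[:, 0], diff[:, 1])
    if np.any(r == 0.0):
        warnings.warn("taxis: neighbour coincident with head skipped", stacklevel=2)
    keep = (r > r_min) & (r > 0.0) & (r <= cutoff)
    if not np.any(keep):
        return np.zeros(2)
    return f_t * (diff[keep] / (r[keep, None] ** 2)).sum(axis=0)


def taxis_drive_all(
    heads: np.ndarray, f_t: float, cutoff: float, side: float, r_min: float = 0.0
) -> np.ndarray:
    """Vectorised taxis drive for every worm's head, (N, 2)."""
    N = heads.shape[0]
    if f_t == 0.0 or N < 2:
        return np.zeros((N, 2))
    diff = min_image(heads[None, :, :] - heads[:, None, :], side)  # i -> j
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(r2, np.inf)
    w = np.where((r2 > r_min * r_min) & (r2 <= cutoff * cutoff), 1.0 / r2, 0.0)
    return f_t * np.einsum("ij,ijk->ik", w, diff)


# ---------------------------------------------------------------------------
# Heading
# ---------------------------------------------------------------------------

def update_heading(
    headings: np.ndarray | float,
    taxis_vec: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator | None = None,
    normals: np.ndarray | None = None,
) -> np.ndarray | float:
    """Persistent-random-walk heading update (vectorised).

    The new deterministic direction is that of the combined motile force
    — the unit persistence vector plus the taxis drive scaled by ``dt``
    — and a Gaussian increment of variance ``2 * D_theta * dt`` is added
    on top.  The ``dt`` scaling makes the taxis drive a turn *rate*
    (rad/s for small drives), so the trajectory is independent of the
    integration step; a drive much larger than ``1/dt`` aligns the
    heading with the neighbour direction within a single step.  With
    zero noise and zero taxis the heading is unchanged.
    """
    scalar = np.isscalar(headings)
    th = np.atleast_1d(np.asarray(headings, dtype=float))
    tx = np.atleast_2d(np.asarray(taxis_vec, dtype=float))
    F = np.stack([np.cos(th), np.sin(th)], axis=1) + params.dt * tx
    norm = np.hypot(F[:, 0], F[:, 1])
    new = np.where(norm > 0.0, np.arctan2(F[:, 1], F[:, 0]), th)
    if normals is None:
        normals = rng.standard_normal(th.shape[0]) if rng is not None else np.zeros(th.shape[0])
    new = new + np.sqrt(2.0 * params.D_theta * params.dt) * normals
    return float(new[0]) if scalar else new


# ---------------------------------------------------------------------------
# Body mechanics
# ---------------------------------------------------------------------------

def advance_body(
    worm: WormState,
    speed: float,
    params: ModelParams,
) -> WormState:
    """Advance one worm chain by one step (leader + follow-the-body).

    The leading node (head, or tail while reversing) moves
    ``speed * dt`` along the worm's heading; trailing nodes are placed at
    the rest spacing towards their already-updated anterior neighbour
    (stiff-spring limit, so the chain length is conserved exactly).
    """
    pos = worm.nodes[None, :, :].astype(float)
    follow_chains(
        pos,
        np.array([worm.heading]),
        np.array([speed * params.dt]),
        params.rest_spacing,
        np.array([worm.reversing]),
    )
    worm.nodes[:] = pos[0]
    return worm


# ---------------------------------------------------------------------------
# Stochastic behaviour updates
# ---------------------------------------------------------------------------

def reversal_probability(rho: np.ndarray | float, r_prime: float, dt: float) -> np.ndarray | float:
    """Per-step probability of initiating a reversal, ``1 - exp(-r' rho dt)``."""
    return -np.expm1(-r_prime * np.asarray(rho, dtype=float) * dt)


def switching_rates(
    rho: np.ndarray | float,
    food_present: np.ndarray | bool,
    params: ModelParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Density-dependent slowing and speeding rates ``(k_slow, k_fast)``.

    ``k_slow`` rises linearly with density and is suppressed to zero
    where food is absent (worms keep moving fast off food); ``k_fast``
    decays exponentially so it stays positive at any density.
    """
    rho = np.asarray(rho, dtype=float)
    k_slow = (params.k_s0 + params.k_s_prime * rho) * np.asarray(food_present, dtype=float)
    k_fast = params.k_f0 * np.exp(-params.k_f_prime * rho)
    return k_slow, np.broadcast_to(k_fast, k_slow.shape).copy()


def reversal_update(
    state: SimulationState,
    rho: np.ndarray,
    params: ModelParams,
    contacts: np.ndarray | None = None,
    uniforms: np.ndarray | None = None,
) -> None:
    """Start, continue and terminate reversals (in place, all worms).

    Contact is sensed by the first and last 10% of nodes within
    ``r_contact``.  A forward worm with contact at exactly one end — a
    worm leaving a cluster — starts a reversal with probability
    ``1 - exp(-r' rho dt)``; both-end (inside a cluster) or no-end
    contact never triggers one.  Ongoing reversals swap the propulsion
    direction head<->tail and end after an exponential duration.
    """
    N = state.n_worms
    if contacts is None:
        contacts = end_contacts(
            state.pos, params.arena_side, params.r_contact, params.n_end_nodes
        )
    if uniforms is None:
        uniforms = state.rng.uniform(size=N)

    # terminate expired reversals first (heading reverts to the head end)
    state.rev_time_left[state.reversing] -= params.dt
    done = state.reversing & (state.rev_time_left <= 0.0)
    if np.any(done):
        head_dir = state.pos[done, 0] - state.pos[done, 1]
        state.headings[done] = np.arctan2(head_dir[:, 1], head_dir[:, 0])
        state.reversing[done] = False
        state.rev_time_left[done] = 0.0

    one_end = contacts[:, 0] ^ contacts[:, 1]
    p = reversal_probability(rho, params.r_prime, params.dt)
    start = (~state.reversing) & one_end & (uniforms < p)
    if np.any(start):
        n = int(start.sum())
        durations = state.rng.exponential(params.reversal_duration_mean, size=n)
        tail_dir = state.pos[start, -1] - state.pos[start, -2]
        state.headings[start] = np.arctan2(tail_dir[:, 1], tail_dir[:, 0])
        state.reversing[start] = True
        state.rev_time_left[start] = durations


def speed_state_update(
    state: SimulationState,
    rho: np.ndarray,
    food_present: np.ndarray | bool,
    params: ModelParams,
    uniforms: np.ndarray | None = None,
) -> None:
    """Poisson switching between slow and fast crawling (in place)."""
    N = state.n_worms
    if uniforms is None:
        uniforms = state.rng.uniform(size=N)
    k_slow, k_fast = switching_rates(rho, food_present, params)
    p_slow = -np.expm1(-k_slow * params.dt)
    p_fast = -np.expm1(-k_fast * params.dt)
    to_slow = state.fast & (uniforms < p_slow)
    to_fast = (~state.fast) & (uniforms < p_fast)
    state.fast[to_slow] = False
    state.fast[to_fast] = True


# ---------------------------------------------------------------------------
# Density sensing
# ---------------------------------------------------------------------------

def knn_density_periodic(points: np.ndarray, k: int, side: float) -> np.ndarray:
    """k-NN areal density of every point in a periodic square, mm^-2.

    Returns zeros when there are fewer than ``k + 1`` points (density is
    then not sensed rather than an error, so tiny test systems still run).
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n <= k:
        return np.zeros(n)
    diff = min_image(pts[None, :, :] - pts[:, None, :], side)
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(d2, np.inf)
    dk2 = np.partition(d2, k - 1, axis=1)[:, k - 1]
    return k / (np.pi * dk2)


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------

def step(state: SimulationState, params: ModelParams, food_enabled: bool = False) -> None:
    """Advance the whole simulation by one time step ``dt``.

    Update order (and RNG draw order): density sensing, taxis, reversal
    uniforms + exponential durations, switching uniforms, heading
    normals, body advance, food depletion.
    """
    heads = state.head_centroids(params)
    # density sensing and taxis share one pairwise minimum-image geometry
    N = state.n_worms
    k = params.knn_k
    diff = min_image(heads[None, :, :] - heads[:, None, :], params.arena_side)
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(r2, np.inf)
    if N > k:
        dk2 = np.partition(r2, k - 1, axis=1)[:, k - 1]
        rho = k / (np.pi * dk2)
    else:
        rho = np.zeros(N)
    if params.f_t > 0.0 and N > 1:
        cutoff, r_min = params.taxis_cutoff, params.taxis_softening
        w = np.where((r2 > r_min * r_min) & (r2 <= cutoff * cutoff), 1.0 / r2, 0.0)
        taxis = params.f_t * np.einsum("ij,ijk->ik", w, diff)
        taxis[state.reversing] = 0.0  # taxis is head-led; backing worms just diffuse
    else:
        taxis = np.zeros((N, 2))

    rev_u = state.rng.uniform(size=state.n_worms)
    reversal_update(state, rho, params, uniforms=rev_u)

    if food_enabled and state.food is not None:
        food_present = local_food(state.food, heads, params.food_threshold)
    else:
        food_present = np.ones(N, dtype=bool)
    sw_u = state.rng.uniform(size=N)
    speed_state_update(state, rho, food_present, params, uniforms=sw_u)

    normals = state.rng.standard_normal(N)
    state.headings = np.asarray(
        update_heading(state.headings, taxis, params, normals=normals)
    )

    speeds = np.where(state.fast, params.v_fast, params.v_slow)
    follow_chains(
        state.pos, state.headings, speeds * params.dt, params.rest_spacing, state.reversing
    )

    if food_enabled and state.food is not None and params.feed_rate > 0.0:
        deplete_step(state.food, heads, params.feed_rate, params.dt)

    # re-centre each worm so its head stays inside the box (whole-worm shift
    # by multiples of the side leaves all geometry unchanged)
    shift = params.arena_side * np.floor(state.pos[:, 0, :] / params.arena_side)
    state.pos -= shift[:, None, :]
    state.time += params.dt

    if not np.all(np.isfinite(state.pos)):
        bad = np.where(~np.isfinite(state.pos).all(axis=(1, 2)))[0]
        raise FloatingPointError(
            f"non-finite coordinates at t={state.time:.2f}s for worms {bad.tolist()}"
        )


def run_simulation(
    params: ModelParams,
    duration: float,
    record_every: float = 30.0,
    food_enabled: bool = False,
    record_skeletons: bool = False,
    record_food_every: float | None = None,
    seed: int | None = None,
) -> TrajectoryDataset:
    """Run the model and record head-region centroids (and optionally more).

    Parameters
    ----------
    duration : float
        Simulated time, s.
    record_every : float
        Sampling interval of the recorded trajectory, s.
    food_enabled : bool
        Couple the worms to a depletable food lawn (swarming mode).
    record_skeletons : bool
        Also store the full (M, 2) skeleton per worm per frame.
    record_food_every : float, optional
        Interval at which food-grid snapshots are stored.

    Returns
    -------
    TrajectoryDataset
        Wrapped coordinates in ``[0, arena_side)``; reproducible given
        the seed (default ``params.seed``).
    """
    if not (duration >= record_every > 0):
        raise ValueError("need duration >= record_every > 0")
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    state = initialize_state(params, rng=rng, food_enabled=food_enabled)

    n_steps = int(round(duration / params.dt))
    stride = max(1, int(round(record_every / params.dt)))
    food_stride = (
        max(1, int(round(record_food_every / params.dt))) if record_food_every else None
    )
    side = params.arena_side

    times, cents, skels, food_times, food_snaps = [], [], [], [], []
    for s in range(1, n_steps + 1):
        step(state, params, food_enabled=food_enabled)
        if s % stride == 0:
            times.append(state.time)
            cents.append(state.head_centroids(params))
            if record_skeletons:
                skels.append(np.mod(state.pos, side))
        if food_stride and state.food is not None and s % food_stride == 0:
            food_times.append(state.time)
            food_snaps.append(state.food.grid.copy())

    return TrajectoryDataset(
        times=np.array(times),
        centroids=np.stack(cents, axis=0) if cents else np.empty((0, params.N, 2)),
        skeletons=np.stack(skels, axis=0) if skels else None,
        arena_side=side,
        provenance="simulated",
        seed=seed,
        params=params.to_dict(),
        food_times=np.array(food_times) if food_snaps else None,
        food_snapshots=np.stack(food_snaps) if food_snaps else None,
        food_cell=params.food_cell if food_snaps else None,
    )
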