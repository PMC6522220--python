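"""Rejection ABC over the behavioural parameters, and the phase sweep.

The four free parameters — reversal slope r', slowing slope k_s',
speeding decay k_f' and taxis strength f_t — are inferred by simulating
from a uniform (feasibility-constrained) prior, summarising each
simulation with the S1–S4 statistics, and accepting the fraction of
parameter draws whose summary statistics lie closest to the target's,
with all four statistics weighted equally after normalisation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .model import run_simulation
from .params import ModelParams
from .stats import SummaryStatSet, summarize_dataset

__all__ = [
    "PriorSpec",
    "PosteriorSamples",
    "sample_prior",
    "compute_normalizers",
    "stat_distance",
    "abc_reject",
    "simulate_for_inference",
    "phase_sweep",
]

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "r_prime": (0.0, 1.0),
    "k_s_prime": (0.0, 1.0),
    "k_f_prime": (0.0, 2.0),
    "f_t": (0.0, 2.0),
}


@dataclass
class PriorSpec:
    """Uniform prior bounds plus an optional feasibility constraint.

    The default constraint caps the reversal rate a parameter draw could
    produce at a crowded-cluster density (``max_reversal_rate``, 1/s at
    ``rho_max`` mm^-2), excluding unrealistically high reversal rates
    for a given worm count.
    """

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    max_reversal_rate: float | None = 2.0
    rho_max: float = 8.0
    constraint: Callable[[dict[str, float]], bool] | None = None

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior bounds for {name} must satisfy lower < upper")

    def feasible(self, theta: dict[str, float]) -> bool:
        if self.max_reversal_rate is not None and "r_prime" in theta:
            if theta["r_prime"] * self.rho_max > self.max_reversal_rate:
                return False
        if self.constraint is not None and not self.constraint(theta):
            return False
        return True

    @property
    def names(self) -> list[str]:
        return list(self.bounds)


def sample_prior(
    spec: PriorSpec,
    n: int,
    seed: int | np.random.Generator | None = 0,
) -> list[dict[str, float]]:
    """Draw ``n`` feasible parameter vectors uniformly within the bounds.

    Infeasible draws are rejected and resampled, so the result is
    uniform on the feasible region.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[dict[str, float]] = []
    attempts = 0
    while len(out) < n:
        theta = {
            name: float(rng.uniform(lo, hi)) for name, (lo, hi) in spec.bounds.items()
        }
        attempts += 1
        if spec.feasible(theta):
            out.append(theta)
        if attempts > 1000 * max(1, n) and not out:
            raise ValueError("feasible region of the prior appears to be empty")
    return out


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _components(a: SummaryStatSet, b: SummaryStatSet) -> np.ndarray:
    if a.s1.shape != b.s1.shape or a.s2.shape != b.s2.shape:
        raise ValueError("summary statistic sets have mismatched binning")
    d1 = float(np.linalg.norm(np.nan_to_num(a.s1 - b.s1)))
    d2 = float(np.linalg.norm(a.s2 - b.s2))
    d3 = abs(a.s3 - b.s3)
    d4 = abs(a.s4 - b.s4)
    return np.array([d1, d2, d3, d4])


def compute_normalizers(sets: Sequence[SummaryStatSet]) -> np.ndarray:
    """Per-statistic scales: RMS component distance to the ensemble mean.

    Self-normalising choice for "equal weighting" of the four summary
    statistics across a prior-predictive ensemble.
    """
    mean = SummaryStatSet(
        s1=np.nanmean(np.stack([s.s1 for s in sets]), axis=0),
        s2=np.mean(np.stack([s.s2 for s in sets]), axis=0),
        s3=float(np.mean([s.s3 for s in sets])),
        s4=float(np.mean([s.s4 for s in sets])),
        s1_edges=sets[0].s1_edges,
        s2_edges=sets[0].s2_edges,
    )
    comp = np.stack([_components(s, mean) for s in sets])
    sig = np.sqrt((comp**2).mean(axis=0))
    sig[sig == 0] = 1.0
    return sig


def stat_distance(
    a: SummaryStatSet,
    b: SummaryStatSet,
    normalizers: np.ndarray | Sequence[float] = (1.0, 1.0, 1.0, 1.0),
) -> float:
    """Equally weighted distance between two summary statistic sets.

    ``d = sum_i d_i / sigma_i`` with Euclidean distances between the S1
    and S2 curves and absolute differences of S3 and S4.  Symmetric, and
    zero iff the component statistics are equal.
    """
    sig = np.asarray(normalizers, dtype=float)
    return float((_components(a, b) / sig).sum())


# ---------------------------------------------------------------------------
# Rejection sampling
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Accepted parameter draws of a rejection-ABC run."""

    names: list[str]
    accepted: np.ndarray        # (n_accept, n_params)
    distances: np.ndarray       # (n_accept,) sorted ascending
    acceptance_fraction: float
    best: dict[str, float]      # closest-matching parameter set

    def marginal(self, name: str) -> np.ndarray:
        return self.accepted[:, self.names.index(name)]

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for i, name in enumerate(self.names):
            col = self.accepted[:, i]
            out[name] = {
                "mean": float(col.mean()),
                "q10": float(np.quantile(col, 0.1)),
                "q50": float(np.quantile(col, 0.5)),
                "q90": float(np.quantile(col, 0.9)),
            }
        return out

    def credible_interval(self, name: str, level: float = 0.8) -> tuple[float, float]:
        col = self.marginal(name)
        half = (1.0 - level) / 2.0
        return float(np.quantile(col, half)), float(np.quantile(col, 1.0 - half))


def abc_reject(
    simulated: Sequence[tuple[dict[str, float], SummaryStatSet]],
    target: SummaryStatSet,
    accept_fraction: float = 0.01,
    normalizers: np.ndarray | None = None,
) -> PosteriorSamples:
    """Accept the ``accept_fraction`` of simulations closest to the target.

    Normalisers default to the prior-predictive scales of the simulated
    ensemble.  Ties at the acceptance boundary are broken by sample
    order (stable sort).
    """
    if not simulated:
        raise ValueError("need at least one simulated (params, stats) pair")
    if not 0 < accept_fraction <= 1:
        raise ValueError("accept_fraction must be in (0, 1]")
    if normalizers is None:
        normalizers = compute_normalizers([s for _, s in simulated])
    names = list(simulated[0][0])
    dists = np.array([stat_distance(s, target, normalizers) for _, s in simulated])
    order = np.argsort(dists, kind="stable")
    n_acc = int(np.ceil(accept_fraction * len(simulated)))
    acc = order[:n_acc]
    accepted = np.array([[simulated[i][0][n] for n in names] for i in acc])
    return PosteriorSamples(
        names=names,
        accepted=accepted,
        distances=dists[acc],
        acceptance_fraction=n_acc / len(simulated),
        best=dict(simulated[acc[0]][0]),
    )


def simulate_for_inference(
    theta: dict[str, float],
    base_params: ModelParams,
    duration: float,
    record_every: float = 30.0,
    seed: int = 0,
    **summary_kw,
) -> SummaryStatSet:
    """Run one simulation at ``theta`` and summarise it."""
    params = base_params.replace(**theta, seed=seed)
    ds = run_simulation(params, duration=duration, record_every=record_every, seed=seed)
    return summarize_dataset(ds, **summary_kw)


# ---------------------------------------------------------------------------
# Phase sweep
# ---------------------------------------------------------------------------

def phase_sweep(
    r_prime_grid: Sequence[float],
    k_prime_grid: Sequence[float],
    base_params: ModelParams,
    replicates: int = 1,
    duration: float = 600.0,
    record_every: float = 30.0,
    seed: int = 0,
    **summary_kw,
) -> dict[tuple[float, float], list[SummaryStatSet]]:
    """Coarse (r', k') portrait of the two-parameter (pre-taxis) model.

    For every grid cell the slowing and speeding density dependences are
    set equal (``k_s' = k_f' = k'``), taxis is off, and each replicate
    run is summarised over the last 10% of its frames.
    """
    if base_params.f_t != 0.0:
        base_params = base_params.replace(f_t=0.0)
    out: dict[tuple[float, float], list[SummaryStatSet]] = {}
    run_idx = 0
    for r in r_prime_grid:
        for k in k_prime_grid:
            cell = []
            for rep in range(replicates):
                params = base_params.replace(
                    r_prime=float(r), k_s_prime=float(k), k_f_prime=float(k),
                    seed=seed + run_idx,
                )
                ds = run_simulation(
                    params, duration=duration, record_every=record_every,
                    seed=seed + run_idx,
                )
                cell.append(summarize_dataset(ds, **summary_kw))
                run_idx += 1
            out[(float(r), float(k))] = cell
    return out
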