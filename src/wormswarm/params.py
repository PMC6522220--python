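"""Model parameters for the worm aggregation simulator.

All quantities are in millimetres and seconds; areal densities in mm^-2.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

__all__ = ["ModelParams", "npr1_reference", "n2_reference"]


@dataclass
class ModelParams:
    """Full parameter set for the agent-based worm model.

    The four behavioural parameters that differ between social (npr-1-like)
    and solitary (N2-like) strains are ``r_prime`` (density slope of the
    cluster-edge reversal rate), ``k_s_prime`` (density slope of the
    slowing-down rate), ``k_f_prime`` (density decay of the speeding-up
    rate) and ``f_t`` (strength of taxis towards neighbours).

    Parameters
    ----------
    N : int
        Number of worms in the arena.
    M : int
        Nodes per worm chain; adjacent nodes are kept at rest spacing
        ``L / (M - 1)``.
    L : float
        Worm length, mm.
    v_fast, v_slow : float
        Crawling speeds of the fast (roaming-like) and slow (dwelling-like)
        motility states, mm/s.
    dt : float
        Integration time step, s.
    D_theta : float
        Rotational diffusion coefficient of the leading-end heading,
        rad^2/s.  Sets the persistence of the random walk.
    r_prime : float
        Slope of the reversal rate with local density, mm^2/s.  The
        reversal rate is ``r_prime * rho`` — zero at zero density, so
        isolated worms never reverse spontaneously.
    k_s0, k_f0 : float
        Zero-density slowing and speeding rates, 1/s.
    k_s_prime : float
        Density slope of the slowing rate: ``k_slow = k_s0 + k_s_prime*rho``.
    k_f_prime : float
        Density decay of the speeding rate:
        ``k_fast = k_f0 * exp(-k_f_prime*rho)`` (exponential form keeps the
        rate positive), mm^2.
    f_t : float
        Taxis weight: neighbours within ``taxis_cutoff`` pull the heading
        with force ``f_t / r`` each.
    r_contact : float
        Contact-sensing radius for the head/tail end nodes, mm.
    taxis_cutoff : float or None
        Interaction range of taxis, mm.  ``None`` means one worm length.
    taxis_softening : float
        Distance at which the 1/r taxis weight saturates, mm (a quarter
        worm length by default).  Heads closer than this exert a
        constant, finite pull, preventing unphysical point collapse of
        overlapping worms.
    arena_side : float
        Side of the periodic square arena, mm.
    reversal_duration_mean : float
        Mean of the exponential reversal duration, s.
    feed_rate : float
        Food consumed per worm per second in the occupied grid cell
        (relative concentration units / s).
    food_threshold : float
        Relative concentration below which a cell counts as food-free.
    food_cell : float
        Food grid cell size, mm.
    knn_k : int
        k of the k-nearest-neighbour density estimate used for sensing.
    seed : int
        Default RNG seed for simulations started from these parameters.
    """

    N: int = 40
    M: int = 18
    L: float = 1.0
    v_fast: float = 0.35
    v_slow: float = 0.035
    dt: float = 0.05
    D_theta: float = 0.1
    r_prime: float = 0.0
    k_s0: float = 1.0 / 240.0
    k_f0: float = 1.0 / 60.0
    k_s_prime: float = 0.0
    k_f_prime: float = 0.0
    f_t: float = 0.0
    r_contact: float = 0.1
    taxis_cutoff: float | None = None
    taxis_softening: float = 0.25
    arena_side: float = 8.0
    reversal_duration_mean: float = 2.0
    feed_rate: float = 2e-3
    food_threshold: float = 0.05
    food_cell: float = 0.2
    knn_k: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.taxis_cutoff is None:
            self.taxis_cutoff = self.L
        self.validate()

    def validate(self) -> None:
        nonneg = (
            "L", "v_fast", "v_slow", "D_theta", "r_prime", "k_s0", "k_f0",
            "k_s_prime", "k_f_prime", "f_t", "r_contact", "taxis_softening",
            "reversal_duration_mean", "feed_rate", "food_threshold",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.M < 3:
            raise ValueError("M must be >= 3")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.taxis_cutoff <= 0:
            raise ValueError("taxis_cutoff must be > 0")
        if self.v_slow > self.v_fast:
            raise ValueError("v_slow must not exceed v_fast")
        if self.arena_side <= self.L:
            raise ValueError("arena_side must exceed the worm length L")
        if self.knn_k < 1 or self.knn_k >= self.N and self.N > 1:
            # sensing needs at least k other worms
            if self.N > 1:
                raise ValueError("knn_k must satisfy 1 <= knn_k < N")

    # -- derived geometry ------------------------------------------------
    @property
    def rest_spacing(self) -> float:
        """Rest distance between adjacent chain nodes, mm."""
        return self.L / (self.M - 1)

    @property
    def n_end_nodes(self) -> int:
        """Nodes at each end used for contact sensing (10% of the chain)."""
        return max(1, int(-(-self.M // 10)))  # ceil(0.1*M)

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kw: Any) -> "ModelParams":
        return dataclasses.replace(self, **kw)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_toml(cls, path: str | Path) -> "ModelParams":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        # accept either a flat file or a [model] table
        if "model" in data and isinstance(data["model"], dict):
            data = data["model"]
        return cls.from_dict(data)


def npr1_reference(**overrides: Any) -> ModelParams:
    """Reference parameter set reproducing npr-1-like aggregation.

    The behavioural parameters (r', k_s', k_f', f_t) are this package's
    reference values, chosen so that simulations aggregate into compact,
    dynamic clusters: frequent cluster-edge reversals, strong
    density-dependent slowing, and medium-range taxis.
    """
    base = dict(
        r_prime=0.2,
        k_s_prime=0.015,
        k_f_prime=0.2,
        f_t=0.1,
    )
    base.update(overrides)
    return ModelParams(**base)


def n2_reference(**overrides: Any) -> ModelParams:
    """Reference parameter set for N2-like (solitary) behaviour.

    Reversals and taxis are weaker than in the npr-1-like set and the
    density dependence of speed switching is mild, so only transient,
    loose groups form.
    """
    base = dict(
        r_prime=0.02,
        k_s_prime=0.005,
        k_f_prime=0.2,
        f_t=0.02,
    )
    base.update(overrides)
    return ModelParams(**base)
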