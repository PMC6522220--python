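"""Periodic food lawn with local depletion by feeding worms."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FoodField", "deplete_step", "local_food"]


@dataclass
class FoodField:
    """2-D grid of relative food concentration in [0, 1].

    The grid covers a periodic square arena; cell (i, j) spans
    ``[i*cell_size, (i+1)*cell_size) x [j*cell_size, (j+1)*cell_size)``
    with axis 0 = x and axis 1 = y.
    """

    grid: np.ndarray
    cell_size: float
    periodic: bool = True

    @classmethod
    def uniform(cls, arena_side: float, cell_size: float, value: float = 1.0) -> "FoodField":
        n = int(round(arena_side / cell_size))
        if n < 1:
            raise ValueError("arena smaller than one food cell")
        return cls(grid=np.full((n, n), float(value)), cell_size=arena_side / n)

    @property
    def side(self) -> float:
        return self.grid.shape[0] * self.cell_size

    def cell_index(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Grid indices of (n, 2) positions (wrapped periodically)."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        n0, n1 = self.grid.shape
        i = np.floor(pos[:, 0] / self.cell_size).astype(np.intp) % n0
        j = np.floor(pos[:, 1] / self.cell_size).astype(np.intp) % n1
        return i, j

    def total(self) -> float:
        return float(self.grid.sum())


def deplete_step(
    food: FoodField,
    worm_positions: np.ndarray,
    feed_rate: float,
    dt: float,
) -> FoodField:
    """Deplete the cells occupied by worm heads, in place.

    Each cell containing at least one worm position loses
    ``feed_rate * dt`` per occupant, floored at zero.  Returns ``food``
    for convenience.
    """
    if feed_rate < 0:
        raise ValueError("feed_rate must be >= 0")
    worm_positions = np.asarray(worm_positions, dtype=float)
    if worm_positions.size == 0 or feed_rate == 0.0:
        return food
    i, j = food.cell_index(worm_positions)
    np.subtract.at(food.grid, (i, j), feed_rate * dt)
    np.maximum(food.grid, 0.0, out=food.grid)
    return food


def local_food(food: FoodField, position: np.ndarray, threshold: float) -> np.ndarray:
    """True where the cell containing ``position`` holds >= ``threshold`` food.

    Accepts a single (2,) position or an (n, 2) array; returns a scalar
    bool or a boolean array accordingly.  The boundary convention is
    inclusive: a cell at exactly the threshold still counts as food.
    """
    pos = np.asarray(position, dtype=float)
    single = pos.ndim == 1
    i, j = food.cell_index(pos)
    ok = food.grid[i, j] >= threshold
    return bool(ok[0]) if single else ok
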