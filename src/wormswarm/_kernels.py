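"""Numba-accelerated inner kernels of the simulation step.

These kernels are pure functions of their array arguments (all randomness
is drawn outside), so the Python-level operations in :mod:`wormswarm.model`
and the main simulation loop share a single implementation of the
geometry-heavy parts.
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["follow_chains", "end_contacts", "min_image"]


@njit(cache=True)
def _wrap_diff(d: float, side: float) -> float:
    # minimum-image convention for one coordinate difference
    return d - side * np.round(d / side)


def min_image(diff: np.ndarray, side: float) -> np.ndarray:
    """Minimum-image displacement for a periodic square of side ``side``."""
    return diff - side * np.round(diff / side)


@njit(cache=True)
def follow_chains(
    pos: np.ndarray,          # (N, M, 2) unwrapped node positions, modified in place
    headings: np.ndarray,     # (N,) heading of the currently leading end
    step_len: np.ndarray,     # (N,) speed * dt per worm
    rest: float,              # rest spacing between adjacent nodes
    reversing: np.ndarray,    # (N,) bool; True -> tail leads
) -> None:
    """Advance each worm chain one step (leader propulsion + body follow).

    The leading node advances ``step_len`` along ``headings``; every
    trailing node is then placed at exactly the rest spacing along the
    line towards its (already updated) anterior neighbour.  This is the
    stiff-spring limit of harmonic bonds: spacings are restored to the
    rest length each step, so the chain is non-extensible.
    """
    N, M, _ = pos.shape
    for i in range(N):
        dx = np.cos(headings[i]) * step_len[i]
        dy = np.sin(headings[i]) * step_len[i]
        if not reversing[i]:
            pos[i, 0, 0] += dx
            pos[i, 0, 1] += dy
            for m in range(1, M):
                ux = pos[i, m - 1, 0] - pos[i, m, 0]
                uy = pos[i, m - 1, 1] - pos[i, m, 1]
                r = np.sqrt(ux * ux + uy * uy)
                if r > 0.0:
                    pos[i, m, 0] = pos[i, m - 1, 0] - rest * ux / r
                    pos[i, m, 1] = pos[i, m - 1, 1] - rest * uy / r
        else:
            pos[i, M - 1, 0] += dx
            pos[i, M - 1, 1] += dy
            for m in range(M - 2, -1, -1):
                ux = pos[i, m + 1, 0] - pos[i, m, 0]
                uy = pos[i, m + 1, 1] - pos[i, m, 1]
                r = np.sqrt(ux * ux + uy * uy)
                if r > 0.0:
                    pos[i, m, 0] = pos[i, m + 1, 0] - rest * ux / r
                    pos[i, m, 1] = pos[i, m + 1, 1] - rest * uy / r


@njit(cache=True)
def end_contacts(
    pos: np.ndarray,       # (N, M, 2) node positions (any branch; min-image used)
    side: float,           # periodic arena side
    r_contact: float,      # contact radius
    n_end: int,            # nodes per end that sense contact
) -> np.ndarray:
    """Contact state of the head and tail end of every worm.

    Returns a boolean (N, 2) array: column 0 is True when any node of
    *another* worm lies within ``r_contact`` of one of the first
    ``n_end`` (head) nodes, column 1 likewise for the last ``n_end``
    (tail) nodes.  Distances use the minimum-image convention.
    """
    N, M, _ = pos.shape
    out = np.zeros((N, 2), dtype=np.bool_)
    # per-worm bounding circles for a cheap pair prefilter
    cx = np.empty(N)
    cy = np.empty(N)
    rad = np.empty(N)
    for i in range(N):
        sx = 0.0
        sy = 0.0
        for m in range(M):
            sx += pos[i, m, 0]
            sy += pos[i, m, 1]
        cx[i] = sx / M
        cy[i] = sy / M
        r2max = 0.0
        for m in range(M):
            ddx = pos[i, m, 0] - cx[i]
            ddy = pos[i, m, 1] - cy[i]
            r2 = ddx * ddx + ddy * ddy
            if r2 > r2max:
                r2max = r2
        rad[i] = np.sqrt(r2max)
    rc2 = r_contact * r_contact
    for i in range(N):
        for e in range(2):
            found = False
            for j in range(N):
                if j == i or found:
                    continue
                dcx = _wrap_diff(cx[j] - cx[i], side)
                dcy = _wrap_diff(cy[j] - cy[i], side)
                reach = rad[i] + rad[j] + r_contact
                if dcx * dcx + dcy * dcy > reach * reach:
                    continue
                for a in range(n_end):
                    idx = a if e == 0 else M - 1 - a
                    ax = pos[i, idx, 0]
                    ay = pos[i, idx, 1]
                    for m in range(M):
                        bx = _wrap_diff(pos[j, m, 0] - ax, side)
                        by = _wrap_diff(pos[j, m, 1] - ay, side)
                        if bx * bx + by * by <= rc2:
                            found = True
                            break
                    if found:
                        break
            out[i, e] = found
    return out
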