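"""Single-lymphocyte random walk: the linear-decay limit made literal.

One effector on a square domain packed with tumor cells lyses at most one
cell per hour, so the decay speed is bounded by one cell/hour — the
constant-velocity limit of the kill law with a single effector.  The walker
lyses the tumor cell under it (if still present), then takes an unbiased
step on the lattice.
"""

from __future__ import annotations

import numpy as np

from .series import LysisSeries

__all__ = ["run_walker"]

_MOVES = ((-1, 0), (1, 0), (0, -1), (0, 1))


def run_walker(
    side: int,
    hours: int,
    seed: int = 0,
    skip_lysed: bool = False,
) -> tuple[LysisSeries, np.ndarray]:
    """Walk a single lymphocyte over a side x side tumor block for ``hours``.

    Starts at the bottom-left corner.  Each hour the walker lyses the tumor
    cell at its current site if one remains, then attempts a uniformly
    random 4-neighbor move; moves off the domain are reflected (the walker
    stays put for that hour).  By default revisiting an already-lysed site
    wastes the hour; with ``skip_lysed`` the walker only spends its kill on
    intact cells (same thing) but *moves preferentially* to intact neighbor
    sites when any exist.

    Returns the lysis series (one record per hour, starting at t = 0) and
    the visited path as an ``(hours+1, 2)`` array of (row, col) positions.
    """
    if side < 1:
        raise ValueError("side must be >= 1")
    if hours < 0:
        raise ValueError("hours must be >= 0")
    rng = np.random.default_rng(seed)
    alive = np.ones((side, side), dtype=bool)
    y, x = side - 1, 0  # bottom-left corner
    remaining = side * side
    path = np.empty((hours + 1, 2), dtype=int)
    path[0] = (y, x)
    series = np.empty(hours + 1)
    series[0] = remaining

    for h in range(1, hours + 1):
        if alive[y, x]:
            alive[y, x] = False
            remaining -= 1
        if skip_lysed:
            intact = [
                (y + dy, x + dx)
                for dy, dx in _MOVES
                if 0 <= y + dy < side and 0 <= x + dx < side and alive[y + dy, x + dx]
            ]
            if intact:
                y, x = intact[rng.integers(len(intact))]
            else:
                dy, dx = _MOVES[rng.integers(4)]
                ny, nx = y + dy, x + dx
                if 0 <= ny < side and 0 <= nx < side:
                    y, x = ny, nx
        else:
            dy, dx = _MOVES[rng.integers(4)]
            ny, nx = y + dy, x + dx
            if 0 <= ny < side and 0 <= nx < side:  # reflecting wall: stay put
                y, x = ny, nx
        path[h] = (y, x)
        series[h] = remaining

    out = LysisSeries(np.arange(hours + 1, dtype=float), series)
    out.meta.update({"side": side, "seed": seed, "skip_lysed": skip_lysed})
    return out, path
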