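"""Independent exhaustive-search oracles for the DP aligner tests.

These enumerate every strictly monotone lattice path and integrate the
matching cost directly on the full grid, without touching the solver's
internal tables.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np


def monotone_paths(n: int) -> Iterator[list[tuple[int, int]]]:
    """All strictly increasing lattice paths from (0, 0) to (n-1, n-1)."""

    def rec(i: int, j: int):
        if i == n - 1 and j == n - 1:
            yield [(i, j)]
            return
        for di in range(1, n - i):
            for dj in range(1, n - j):
                for rest in rec(i + di, j + dj):
                    yield [(i, j)] + rest

    yield from rec(0, 0)


def gamma_from_path(grid: np.ndarray, path: list[tuple[int, int]]) -> np.ndarray:
    ii = np.array([a for a, _ in path])
    jj = np.array([b for _, b in path])
    return np.interp(grid, grid[ii], grid[jj])


def objective_on_grid(
    grid: np.ndarray,
    qx: np.ndarray,
    qy: np.ndarray,
    path: list[tuple[int, int]],
    lam: float = 0.0,
) -> float:
    """Directly discretized alignment objective for a piecewise-linear warp.

    Integrates interval by interval on the full grid, using the exact
    constant slope of the segment each interval belongs to.
    """
    gamma = gamma_from_path(grid, path)
    total = 0.0
    seg = 0
    for m in range(grid.size - 1):
        while path[seg + 1][0] <= m:
            seg += 1
        (k, l), (i, j) = path[seg], path[seg + 1]
        slope = (grid[j] - grid[l]) / (grid[i] - grid[k])
        root = np.sqrt(slope)
        va = qx[m] - root * np.interp(gamma[m], grid, qy)
        vb = qx[m + 1] - root * np.interp(gamma[m + 1], grid, qy)
        h = grid[m + 1] - grid[m]
        total += 0.5 * h * (va**2 + vb**2)
        total += lam * (root - 1.0) ** 2 * h
    return total


def exhaustive_minimum(
    grid: np.ndarray,
    qx: np.ndarray,
    qy: np.ndarray,
    delta: float = np.inf,
    lam: float = 0.0,
) -> float:
    """Minimum objective over all monotone paths whose nodes satisfy the band."""
    best = np.inf
    for path in monotone_paths(grid.size):
        if np.isfinite(delta) and any(
            abs(grid[i] - grid[j]) > delta + 1e-12 for i, j in path
        ):
            continue
        best = min(best, objective_on_grid(grid, qx, qy, path, lam))
    return best
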