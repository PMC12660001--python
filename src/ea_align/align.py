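"""Alignment strategies for paired rating curves.

The central solver is a sup-norm-constrained elastic alignment: find the
piecewise-linear warping ``gamma`` minimizing the SRVF matching cost

    E(gamma) = int_0^1 [ q_x(t) - q_y(gamma(t)) sqrt(gamma'(t)) ]^2 dt

subject to ``max_t |gamma(t) - t| <= delta`` (delta expressed in seconds and
normalized by the recording duration).  The constraint encodes the
psychologically plausible reaction-time window: warps are allowed to absorb
short-term misalignment between a perceiver's observed and latent ratings,
but not the genuine disagreement that empathic accuracy is supposed to
measure.

The solver runs dynamic programming on the lattice of grid-point pairs
(i, j), i.e. candidate matchings ``gamma(t_i) = t_j``.  The matching cost is
additive over straight-line lattice segments, so the optimal path (and hence
the globally optimal piecewise-linear warp over the searched lattice) is
found exactly.  Because both the warp and the identity are linear on each
segment, ``|gamma(t) - t|`` attains its maximum at segment endpoints, so
node-level feasibility checks enforce the continuous sup-norm constraint
exactly.

Five strategies share the :class:`AlignmentResult` interface:

``none``
    identity warp (the conventional, alignment-free analysis);
``fixed_delay``
    best constant shift with endpoint clamping;
``srvf_unpenalized``
    unconstrained elastic alignment (delta = infinity);
``srvf_l2_penalized``
    elastic alignment with penalty ``lambda * || sqrt(gamma') - 1 ||^2``
    (squared L2 distance between the SRVF of gamma and of the identity);
``srvf_sup_penalized``
    the sup-norm-constrained alignment described above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import trapezoid

from .curves import (
    RatingCurve,
    Srvf,
    Warping,
    identity_warping,
    srvf_transform,
)
from .errors import InvalidConfigError, InvalidCurveError, InvalidWarpError

__all__ = [
    "AlignmentConfig",
    "AlignmentResult",
    "METHODS",
    "segment_cost",
    "align_pair",
    "align_unpenalized",
    "align_sup_penalized",
    "align_l2_penalized",
    "align_fixed_delay",
    "apply_alignment",
]

METHODS = (
    "none",
    "fixed_delay",
    "srvf_unpenalized",
    "srvf_l2_penalized",
    "srvf_sup_penalized",
)

#: Accumulated-cost ties below this are broken by segment-slope priority.
_TIE_TOL = 1e-12


@dataclass(frozen=True)
class AlignmentConfig:
    """Configuration shared by all aligners.

    Parameters
    ----------
    method
        One of :data:`METHODS`.
    delta_seconds
        Sup-norm warping limit delta in seconds (``inf`` disables the band).
    lambda_penalty
        Penalty weight for the squared-L2 baseline (normalized time scale).
    dp_window
        Predecessor window width W: node (i, j) admits predecessors (k, l)
        with ``i-W <= k < i`` and ``j-W <= l < j``.  Full-window search uses
        ``W = n-1``.
    max_delay_seconds
        Search bound for the fixed-delay baseline.
    """

    method: str = "srvf_sup_penalized"
    delta_seconds: float = 4.0
    lambda_penalty: float = 1.0
    dp_window: int = 7
    max_delay_seconds: float = 10.0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise InvalidConfigError(f"unknown method {self.method!r}")
        if self.delta_seconds < 0:
            raise InvalidConfigError("delta_seconds must be >= 0")
        if self.lambda_penalty < 0:
            raise InvalidConfigError("lambda_penalty must be >= 0")
        if self.dp_window < 1:
            raise InvalidConfigError("dp_window must be >= 1")
        if self.max_delay_seconds < 0:
            raise InvalidConfigError("max_delay_seconds must be >= 0")


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of aligning a perceiver curve to a target curve.

    ``gamma_hat`` is the estimated inverse warping applied to the perceiver
    curve, so ``aligned = y o gamma_hat`` estimates the perceiver's latent
    rating.  ``phase_distance`` is the Fisher-Rao distance of ``gamma_hat``
    from the identity; ``feasible`` records whether the sup-norm constraint
    holds for the reported warp.
    """

    gamma_hat: Warping
    aligned: RatingCurve
    objective: float
    method: str
    delta_seconds_used: float
    phase_distance: float
    feasible: bool


def _check_pair(qx: Srvf, qy: Srvf) -> tuple[np.ndarray, float]:
    if qx.n != qy.n or not np.allclose(qx.grid, qy.grid):
        raise InvalidCurveError("aligner requires a shared grid")
    d = np.diff(qx.grid)
    if not np.allclose(d, d[0], rtol=1e-6, atol=1e-12):
        raise InvalidCurveError("DP aligner requires a uniform grid")
    return qx.grid, float(d[0])


def segment_cost(
    qx: Srvf,
    qy: Srvf,
    from_node: tuple[int, int],
    to_node: tuple[int, int],
    lambda_penalty: float = 0.0,
) -> float:
    """Matching cost of one straight lattice segment.

    The warp is the straight line joining ``(t_k, t_l)`` to ``(t_i, t_j)``,
    so its slope is the constant ``(t_j - t_l) / (t_i - t_k)``; ``q_y`` is
    evaluated by linear interpolation and the integral over ``[t_k, t_i]`` is
    a trapezoid rule on the sub-grid.  The optional penalty adds
    ``lambda * (sqrt(slope) - 1)^2 * (t_i - t_k)``, the exact squared-L2
    identity-deviation of the segment's constant-slope warp.
    """
    grid, _ = _check_pair(qx, qy)
    k, l = from_node
    i, j = to_node
    if not (0 <= k < i < qx.n and 0 <= l <= j < qx.n):
        raise InvalidConfigError(f"invalid segment {from_node} -> {to_node}")
    sub = grid[k : i + 1]
    slope = (grid[j] - grid[l]) / (grid[i] - grid[k])
    gam = grid[l] + slope * (sub - grid[k])
    qy_g = np.interp(gam, grid, qy.q)
    integrand = (qx.q[k : i + 1] - math.sqrt(slope) * qy_g) ** 2
    cost = float(trapezoid(integrand, sub))
    cost += lambda_penalty * (math.sqrt(slope) - 1.0) ** 2 * (grid[i] - grid[k])
    return cost


def _pair_priority(dk: int, dl: int) -> tuple[float, int, int]:
    # slope closest to 1 first; then smallest predecessor k (largest dk),
    # then smallest l (largest dl) — deterministic shrinkage-toward-identity
    return (abs(math.log(dl / dk)), -dk, -dl)


def _segment_tables(
    qx: np.ndarray, qy: np.ndarray, dt: float, pairs: list[tuple[int, int]],
    lam: float,
) -> list[np.ndarray]:
    """Vectorized per-(dk, dl) tables of segment costs for all (k, l)."""
    n = qx.size
    sw = np.lib.stride_tricks.sliding_window_view
    tables: list[np.ndarray] = []
    for dk, dl in pairs:
        m = dk + 1
        slope = dl / dk
        c = math.sqrt(slope)
        # A[s, k] = qx[k + s]
        A = sw(qx, m).T
        # B[s, l] = qy interpolated at fractional index l + s * slope
        pos = np.arange(m) * slope
        ip = np.minimum(np.floor(pos + 1e-12).astype(int), dl)
        frac = np.clip(pos - ip, 0.0, 1.0)
        Qw = sw(qy, dl + 1).T  # Qw[r, l] = qy[l + r]
        B = (1.0 - frac)[:, None] * Qw[ip, :] + frac[:, None] * Qw[
            np.minimum(ip + 1, dl), :
        ]
        w = np.full(m, dt)
        w[0] = w[-1] = 0.5 * dt
        sa = (w[:, None] * A**2).sum(axis=0)  # (n - dk,)
        sb = (w[:, None] * B**2).sum(axis=0)  # (n - dl,)
        cross = (w[:, None] * A).T @ B  # (n - dk, n - dl)
        cost = sa[:, None] + slope * sb[None, :] - 2.0 * c * cross
        cost += lam * (c - 1.0) ** 2 * (dk * dt)
        tables.append(cost)
    return tables


def _dp_solve(
    qx: Srvf,
    qy: Srvf,
    delta_norm: float,
    lam: float,
    window: int,
) -> tuple[np.ndarray, float]:
    """Constrained DP over the matching lattice.

    Returns the piecewise-linear warp evaluated on the full grid and the
    optimal objective value.
    """
    grid, dt = _check_pair(qx, qy)
    n = qx.n
    W = min(window, n - 1)
    pairs = sorted(
        ((dk, dl) for dk in range(1, W + 1) for dl in range(1, W + 1)),
        key=lambda p: _pair_priority(*p),
    )
    seg = _segment_tables(qx.q, qy.q, dt, pairs, lam)
    P = len(pairs)

    feas = np.abs(grid[None, :] - grid[:, None]) <= delta_norm + 1e-12  # (i, j)
    C = np.full((n, n), np.inf)
    C[0, 0] = 0.0
    pred = np.full((n, n), -1, dtype=np.int32)

    cand = np.empty((P, n))
    for i in range(1, n):
        cand.fill(np.inf)
        for p, (dk, dl) in enumerate(pairs):
            if dk > i:
                continue
            k = i - dk
            cand[p, dl:] = C[k, : n - dl] + seg[p][k, : n - dl]
        best = cand.min(axis=0)
        # first pair (highest priority) within tie tolerance of the minimum
        choice = np.argmax(cand <= best[None, :] + _TIE_TOL, axis=0)
        row = np.where(feas[i], best, np.inf)
        C[i, :] = row
        pred[i, :] = np.where(np.isfinite(row), choice, -1)

    if not np.isfinite(C[n - 1, n - 1]):
        raise AssertionError(
            "no feasible DP path; the diagonal should always be feasible"
        )

    # backtrack
    i = j = n - 1
    nodes = [(i, j)]
    while (i, j) != (0, 0):
        p = pred[i, j]
        if p < 0:
            raise AssertionError("broken back-pointer chain in DP lattice")
        dk, dl = pairs[p]
        i, j = i - dk, j - dl
        nodes.append((i, j))
    nodes.reverse()
    ii = np.array([a for a, _ in nodes])
    jj = np.array([b for _, b in nodes])
    gamma = np.interp(grid, grid[ii], grid[jj])
    gamma[0], gamma[-1] = 0.0, 1.0
    return gamma, float(C[n - 1, n - 1])


def apply_alignment(y: RatingCurve, g: Warping) -> RatingCurve:
    """Compose a curve with a warp: (y o gamma)(t_k) by linear interpolation."""
    vals = np.interp(g.gamma, y.grid, y.values)
    return y.with_values(vals, label="aligned")


def _phase_distance(g: Warping) -> float:
    # local import would be circular the other way; metrics re-exports this
    from .metrics import fisher_rao_phase_distance

    return fisher_rao_phase_distance(g)


def _result(
    y: RatingCurve,
    gamma: Warping,
    objective: float,
    method: str,
    delta_seconds: float,
) -> AlignmentResult:
    aligned = apply_alignment(y, gamma)
    feasible = (
        gamma.sup_dev * y.duration_seconds <= delta_seconds + 1e-9
        if np.isfinite(delta_seconds)
        else True
    )
    return AlignmentResult(
        gamma_hat=gamma,
        aligned=aligned,
        objective=max(objective, 0.0),
        method=method,
        delta_seconds_used=delta_seconds,
        phase_distance=_phase_distance(gamma),
        feasible=feasible,
    )


def align_unpenalized(
    qx: Srvf, qy: Srvf, y: RatingCurve, cfg: AlignmentConfig
) -> AlignmentResult:
    """Unconstrained elastic alignment (the band is inactive)."""
    gamma, obj = _dp_solve(qx, qy, np.inf, 0.0, cfg.dp_window)
    g = Warping(grid=qx.grid, gamma=gamma)
    return _result(y, g, obj, "srvf_unpenalized", math.inf)


def align_sup_penalized(
    qx: Srvf, qy: Srvf, y: RatingCurve, cfg: AlignmentConfig
) -> AlignmentResult:
    """Sup-norm-constrained elastic alignment at ``cfg.delta_seconds``."""
    delta_norm = cfg.delta_seconds / y.duration_seconds
    gamma, obj = _dp_solve(qx, qy, delta_norm, 0.0, cfg.dp_window)
    g = Warping(grid=qx.grid, gamma=gamma)
    return _result(y, g, obj, "srvf_sup_penalized", cfg.delta_seconds)


def align_l2_penalized(
    qx: Srvf, qy: Srvf, y: RatingCurve, cfg: AlignmentConfig
) -> AlignmentResult:
    """Elastic alignment with squared-L2 identity-deviation penalty."""
    gamma, obj = _dp_solve(qx, qy, np.inf, cfg.lambda_penalty, cfg.dp_window)
    g = Warping(grid=qx.grid, gamma=gamma)
    return _result(y, g, obj, "srvf_l2_penalized", math.inf)


def align_fixed_delay(
    x: RatingCurve, y: RatingCurve, cfg: AlignmentConfig
) -> AlignmentResult:
    """Best constant shift of the perceiver curve, clamped at the boundary.

    The shift Delta is searched on the grid step over
    ``[-max_delay, max_delay]``; ``y_Delta(t) = y(t - Delta)`` with endpoint
    clamping outside the domain.  Ties prefer the smaller ``|Delta|``.
    """
    if cfg.max_delay_seconds >= x.duration_seconds:
        raise InvalidConfigError("max_delay_seconds must be below the duration")
    if x.n != y.n or not np.allclose(x.grid, y.grid):
        raise InvalidCurveError("fixed-delay aligner requires a shared grid")
    grid = x.grid
    dt = grid[1] - grid[0]
    kmax = int(math.floor(cfg.max_delay_seconds / x.duration_seconds / dt))
    n = x.n

    def shifted(k: int) -> np.ndarray:
        # y(t - k*dt) with clamping
        if k == 0:
            return y.values
        out = np.empty(n)
        if k > 0:
            out[:k] = y.values[0]
            out[k:] = y.values[: n - k]
        else:
            out[: n + k] = y.values[-k:]
            out[n + k :] = y.values[-1]
        return out

    best_k, best_cost = 0, np.inf
    for k in sorted(range(-kmax, kmax + 1), key=lambda k: (abs(k), k)):
        vals = shifted(k)
        cost = float(trapezoid((x.values - vals) ** 2, grid))
        if cost < best_cost - _TIE_TOL:
            best_cost, best_k = cost, k
    delta_norm = best_k * dt
    gamma = np.clip(grid - delta_norm, 0.0, 1.0)
    g = Warping(grid=grid, gamma=gamma, boundary_fixed=False)
    aligned = y.with_values(shifted(best_k), label="aligned")
    return AlignmentResult(
        gamma_hat=g,
        aligned=aligned,
        objective=best_cost,
        method="fixed_delay",
        delta_seconds_used=math.inf,
        phase_distance=_phase_distance(g),
        feasible=True,
    )


def align_pair(
    x: RatingCurve, y: RatingCurve, cfg: AlignmentConfig
) -> AlignmentResult:
    """Align a perceiver curve ``y`` to the target ``x`` with ``cfg.method``.

    The target's timeline is the reference; the estimated inverse warp is
    applied to ``y``.
    """
    if x.n != y.n or not np.allclose(x.grid, y.grid):
        raise InvalidCurveError("align_pair requires curves on a shared grid")
    if not math.isclose(x.duration_seconds, y.duration_seconds, rel_tol=1e-9):
        raise InvalidCurveError("curves must share the recording duration")
    if x.n < 3:
        raise InvalidCurveError("alignment needs at least 3 grid points")

    if cfg.method == "none":
        g = identity_warping(x.grid)
        qx, qy = srvf_transform(x), srvf_transform(y)
        obj = float(trapezoid((qx.q - qy.q) ** 2, x.grid))
        return _result(y, g, obj, "none", 0.0)
    if cfg.method == "fixed_delay":
        return align_fixed_delay(x, y, cfg)

    qx, qy = srvf_transform(x), srvf_transform(y)
    if cfg.method == "srvf_unpenalized":
        return align_unpenalized(qx, qy, y, cfg)
    if cfg.method == "srvf_l2_penalized":
        return align_l2_penalized(qx, qy, y, cfg)
    return align_sup_penalized(qx, qy, y, cfg)
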