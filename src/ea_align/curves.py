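"""Domain types and SRVF machinery for scalar rating trajectories.

A rating trajectory is a real-valued function on a closed time interval,
stored on a normalized grid over [0, 1] together with the original span in
seconds.  The square-root velocity function (SRVF) of an absolutely
continuous curve ``f`` is

    q(t) = sign(f'(t)) * sqrt(|f'(t)|),

a representation under which time warping acts by ``(q o gamma) sqrt(gamma')``
and preserves the L2 norm.  That isometry is what makes phase (timing) and
amplitude (value) variation separable, and it is the foundation of every
aligner in :mod:`ea_align.align`.

Numerical conventions used throughout the package:

* derivatives are central finite differences at interior points and
  second-order one-sided differences at the endpoints (``numpy.gradient``);
* every integral is a composite trapezoid rule on the stored grid;
* all computation happens on the normalized domain [0, 1]; quantities in
  seconds (sup-norm limits, delays) are divided by ``duration_seconds`` on
  entry and multiplied back on reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

from .errors import (
    IllConditionedWarpError,
    InvalidCurveError,
    InvalidWarpError,
)

__all__ = [
    "RatingCurve",
    "Srvf",
    "Warping",
    "uniform_grid",
    "derivative",
    "srvf_transform",
    "srvf_inverse",
    "warp_action",
    "compose_warpings",
    "invert_warping",
    "identity_warping",
]

#: Tolerance below which a warping increment counts as "flat".
MONOTONE_TOL = 1e-10


def uniform_grid(n: int) -> np.ndarray:
    """Equidistant grid of ``n`` points on [0, 1]."""
    if n < 3:
        raise InvalidCurveError(f"grid needs at least 3 points, got {n}")
    return np.linspace(0.0, 1.0, n)


def _validate_grid(grid: np.ndarray) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size < 3:
        raise InvalidCurveError("grid must be one-dimensional with >= 3 points")
    if not np.all(np.isfinite(g)):
        raise InvalidCurveError("grid contains non-finite values")
    if abs(g[0]) > 1e-9 or abs(g[-1] - 1.0) > 1e-9:
        raise InvalidCurveError(
            f"grid must be normalized to [0, 1]; got [{g[0]}, {g[-1]}]"
        )
    if np.any(np.diff(g) <= 0):
        raise InvalidCurveError("grid must be strictly increasing")
    g = g.copy()
    g[0], g[-1] = 0.0, 1.0
    return g


def derivative(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Finite-difference derivative (central interior, one-sided 2nd-order ends)."""
    return np.gradient(np.asarray(values, dtype=float), grid, edge_order=2)


@dataclass(frozen=True)
class RatingCurve:
    """A rating trajectory sampled on a normalized time grid.

    Parameters
    ----------
    grid
        Strictly increasing time points normalized to [0, 1].
    values
        Ratings at the grid points.
    duration_seconds
        Original span of the recording in seconds (e.g. 108).
    label
        Free-text role tag: ``"target"``, ``"perceiver"`` or ``"latent"``.
    """

    grid: np.ndarray
    values: np.ndarray
    duration_seconds: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        g = _validate_grid(self.grid)
        v = np.asarray(self.values, dtype=float)
        if v.shape != g.shape:
            raise InvalidCurveError("grid and values must have equal length")
        if not np.all(np.isfinite(v)):
            raise InvalidCurveError("curve values contain non-finite entries")
        if not (self.duration_seconds > 0):
            raise InvalidCurveError("duration_seconds must be positive")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.grid.size

    def l2_norm(self) -> float:
        """L2 norm sqrt(int f^2) on the normalized domain."""
        return float(np.sqrt(trapezoid(self.values**2, self.grid)))

    def with_values(self, values: np.ndarray, label: str | None = None) -> "RatingCurve":
        return replace(
            self, values=np.asarray(values, dtype=float),
            label=self.label if label is None else label,
        )


@dataclass(frozen=True)
class Srvf:
    """Square-root velocity representation of a curve on its grid."""

    grid: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        g = _validate_grid(self.grid)
        q = np.asarray(self.q, dtype=float)
        if q.shape != g.shape:
            raise InvalidCurveError("grid and q must have equal length")
        if not np.all(np.isfinite(q)):
            raise InvalidCurveError("SRVF values contain non-finite entries")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "q", q)

    @property
    def n(self) -> int:
        return self.grid.size

    def norm_squared(self) -> float:
        """Squared L2 norm int q^2 (trapezoid)."""
        return float(trapezoid(self.q**2, self.grid))


@dataclass(frozen=True)
class Warping:
    """Boundary-fixed nondecreasing time reparameterization gamma.

    ``sup_dev`` caches ``max_k |gamma(t_k) - t_k|`` in normalized units; it is
    recomputed on construction so it can never drift from the stored values.
    ``boundary_fixed=False`` relaxes the endpoint constraints; it is used only
    for the clamped shift maps of the fixed-delay baseline, which leave the
    warping group.
    """

    grid: np.ndarray
    gamma: np.ndarray
    boundary_fixed: bool = True
    sup_dev: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        g = _validate_grid(self.grid)
        gam = np.asarray(self.gamma, dtype=float)
        if gam.shape != g.shape:
            raise InvalidWarpError("grid and gamma must have equal length")
        if not np.all(np.isfinite(gam)):
            raise InvalidWarpError("gamma contains non-finite entries")
        if np.any(gam < -1e-9) or np.any(gam > 1 + 1e-9):
            raise InvalidWarpError("gamma values must lie in [0, 1]")
        if np.any(np.diff(gam) < -MONOTONE_TOL):
            raise InvalidWarpError("gamma must be nondecreasing")
        gam = np.clip(gam, 0.0, 1.0)
        if self.boundary_fixed:
            if abs(gam[0]) > 1e-9 or abs(gam[-1] - 1.0) > 1e-9:
                raise InvalidWarpError(
                    f"gamma must fix the boundary; got gamma(0)={gam[0]}, "
                    f"gamma(1)={gam[-1]}"
                )
            gam[0], gam[-1] = 0.0, 1.0
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "gamma", gam)
        object.__setattr__(self, "sup_dev", float(np.max(np.abs(gam - g))))

    @property
    def n(self) -> int:
        return self.grid.size

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Evaluate gamma at arbitrary points by linear interpolation."""
        return np.interp(t, self.grid, self.gamma)


def identity_warping(grid: np.ndarray) -> Warping:
    """The identity element gamma(t) = t on ``grid``."""
    g = _validate_grid(grid)
    return Warping(grid=g, gamma=g.copy())


def srvf_transform(f: RatingCurve) -> Srvf:
    """SRVF of a curve: q = sign(f') sqrt(|f'|).

    Points with zero slope map to exactly 0 (``sign(0) = 0``), which is the
    continuous extension of the transform.
    """
    fd = derivative(f.values, f.grid)
    if not np.all(np.isfinite(fd)):
        raise InvalidCurveError("derivative of curve is non-finite")
    q = np.sign(fd) * np.sqrt(np.abs(fd))
    return Srvf(grid=f.grid, q=q)


def srvf_inverse(q: Srvf, f0: float, duration_seconds: float = 1.0,
                 label: str = "") -> RatingCurve:
    """Invert an SRVF: f(t) = f0 + int_0^t q(s) |q(s)| ds (cumulative trapezoid)."""
    integrand = q.q * np.abs(q.q)
    vals = f0 + cumulative_trapezoid(integrand, q.grid, initial=0.0)
    return RatingCurve(grid=q.grid, values=vals,
                       duration_seconds=duration_seconds, label=label)


def warp_action(q: Srvf, g: Warping) -> Srvf:
    """Group action of a warp on an SRVF: (q o gamma) * sqrt(gamma').

    The action is an isometry of L2 — the squared norm of the output equals
    that of ``q`` up to quadrature error.
    """
    if not g.boundary_fixed:
        raise InvalidWarpError("warp_action requires a boundary-fixed warping")
    gd = derivative(g.gamma, g.grid)
    gd = np.clip(gd, 0.0, None)  # guard tiny negative finite-difference noise
    q_of_gamma = np.interp(g.gamma, q.grid, q.q)
    return Srvf(grid=q.grid, q=q_of_gamma * np.sqrt(gd))


def compose_warpings(g1: Warping, g2: Warping) -> Warping:
    """Composition (g1 o g2)(t) = g1(g2(t)) by linear interpolation."""
    gam = np.interp(g2.gamma, g1.grid, g1.gamma)
    gam[0], gam[-1] = g1.gamma[0], g1.gamma[-1]
    return Warping(grid=g2.grid, gamma=gam,
                   boundary_fixed=g1.boundary_fixed and g2.boundary_fixed)


def invert_warping(g: Warping) -> Warping:
    """Inverse warping gamma^{-1} by monotone interpolation on the same grid.

    Requires gamma to be strictly increasing up to tolerance; a flat segment
    would make the inverse multivalued.
    """
    if not g.boundary_fixed:
        raise InvalidWarpError("only boundary-fixed warpings can be inverted")
    if np.any(np.diff(g.gamma) < MONOTONE_TOL):
        raise IllConditionedWarpError(
            "gamma has a flat segment; inverse is ill-conditioned"
        )
    inv = np.interp(g.grid, g.gamma, g.grid)
    inv[0], inv[-1] = 0.0, 1.0
    return Warping(grid=g.grid, gamma=inv)
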