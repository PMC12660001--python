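"""Preprocessing: raw epoch-sampled Likert ratings -> smooth curves.

Real-time EA studies record ratings at fixed epochs (e.g. every 2 s over
~108 s on a 1-9 scale).  Following standard functional-data practice, each
series is smoothed with a cubic smoothing spline (generalized
cross-validation chooses the penalty unless one is supplied) and evaluated
on an equidistant grid — 300 points by default.  The screening rule removes
perceiver-target pairs whose unaligned Pearson correlation is negative,
since such perceivers plausibly follow a different empathy pattern than the
population under study.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.interpolate import make_interp_spline, make_smoothing_spline

from .curves import RatingCurve, uniform_grid
from .errors import CannotSmoothError, InvalidCurveError, UndefinedCorrelationError

__all__ = [
    "RawRatingSeries",
    "smooth_and_resample",
    "screen_negative_correlation",
    "ScreeningResult",
]


@dataclass(frozen=True)
class RawRatingSeries:
    """An epoch-sampled rating series as recorded.

    ``rating_range`` is validated, never rescaled: correlation and SRVF
    alignment are both invariant to the Likert range.
    """

    times_seconds: np.ndarray
    ratings: np.ndarray
    subject_id: str = ""
    stimulus_id: str = ""
    rating_range: tuple[float, float] = (1.0, 9.0)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_seconds, dtype=float)
        r = np.asarray(self.ratings, dtype=float)
        if t.ndim != 1 or t.size < 3 or r.shape != t.shape:
            raise InvalidCurveError(
                "series needs >= 3 observations with matching times/ratings"
            )
        if np.any(np.diff(t) <= 0):
            raise InvalidCurveError("times_seconds must be increasing")
        lo, hi = self.rating_range
        if np.any(r < lo - 1e-9) or np.any(r > hi + 1e-9):
            raise InvalidCurveError(
                f"ratings outside declared range [{lo}, {hi}]"
            )
        object.__setattr__(self, "times_seconds", t)
        object.__setattr__(self, "ratings", r)


def smooth_and_resample(
    s: RawRatingSeries,
    n_grid: int = 300,
    lam: float | None = None,
    label: str = "",
) -> RatingCurve:
    """Cubic smoothing spline -> equidistant grid -> normalized RatingCurve.

    Parameters
    ----------
    s
        Raw series with at least 4 distinct time points.
    n_grid
        Number of equidistant output points (default 300).
    lam
        Smoothing penalty.  ``None`` (default) selects it by generalized
        cross-validation; ``0`` gives an interpolating cubic spline
        (smoothing disabled).
    """
    if n_grid < 3:
        raise InvalidCurveError("n_grid must be >= 3")
    t = s.times_seconds
    if np.unique(t).size < 4:
        raise CannotSmoothError("need at least 4 distinct times to smooth")
    duration = float(t[-1] - t[0])
    if duration <= 0:
        raise CannotSmoothError("series has zero time span")
    if lam is not None and lam == 0:
        spline = make_interp_spline(t, s.ratings, k=3)
    else:
        spline = make_smoothing_spline(t, s.ratings, lam=lam)
    tt = np.linspace(t[0], t[-1], n_grid)
    vals = spline(tt)
    return RatingCurve(
        grid=uniform_grid(n_grid),
        values=np.asarray(vals, dtype=float),
        duration_seconds=duration,
        label=label,
    )


class ScreeningResult(NamedTuple):
    kept: list[tuple[RatingCurve, RatingCurve]]
    removed: list[tuple[RatingCurve, RatingCurve]]
    undefined: list[tuple[RatingCurve, RatingCurve]]


def screen_negative_correlation(
    pairs: list[tuple[RatingCurve, RatingCurve]],
) -> ScreeningResult:
    """Partition (target, perceiver) pairs by the sign of the unaligned r.

    Pairs with negative identity-warp Pearson correlation are removed.
    Zero-variance pairs have an undefined correlation; they are reported
    separately and excluded from both lists.  Curve values are never
    altered, only membership.
    """
    kept, removed, undefined = [], [], []
    for x, y in pairs:
        if x.n != y.n or not np.allclose(x.grid, y.grid):
            raise InvalidCurveError("screening requires aligned grids")
        sx, sy = np.std(x.values), np.std(y.values)
        if sx <= 0 or sy <= 0:
            undefined.append((x, y))
            continue
        r = float(np.corrcoef(x.values, y.values)[0, 1])
        (removed if r < 0 else kept).append((x, y))
    return ScreeningResult(kept=kept, removed=removed, undefined=undefined)
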