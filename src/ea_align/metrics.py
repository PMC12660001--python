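"""Empathic-accuracy and alignment-diagnostic metrics.

Correlation-based EA measures, the Fisher-Rao phase distance used to
quantify warp amount, the amplitude (L2) distance used in the simulation
studies, and the bias/discrimination/variability mixed model used for the
music-rating analysis.

Correlations are computed on the grid values with equal weights (the
discrete-epoch Pearson convention of EA research), not by functional inner
product.  Fisher-z values are clamped at |r| = 1 - 1e-12 so that downstream
regressions stay finite even when an aggressive aligner reaches r ~ 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid

from .curves import RatingCurve, Warping, derivative
from .errors import InvalidCurveError, UndefinedCorrelationError

__all__ = [
    "EaRecord",
    "MixedModelFit",
    "fisher_rao_phase_distance",
    "ea_correlation",
    "amplitude_distance",
    "correlation_bias",
    "fit_bias_discrimination_model",
    "ea_records_frame",
]

_Z_CLAMP = 1.0 - 1e-12

#: Documented column order for EaRecord tables.
EA_RECORD_COLUMNS = [
    "subject_id",
    "stimulus_id",
    "method",
    "delta_seconds",
    "r_identity",
    "z_identity",
    "r_aligned",
    "z_aligned",
    "phase_distance",
]


@dataclass(frozen=True)
class EaRecord:
    """Per perceiver-stimulus EA summary before and after alignment."""

    subject_id: str
    stimulus_id: str
    r_identity: float
    r_aligned: float
    z_identity: float
    z_aligned: float
    phase_distance: float
    method: str
    delta_seconds: float


def ea_records_frame(records: list[EaRecord]) -> pd.DataFrame:
    """EaRecord list as a DataFrame in the documented column order."""
    rows = [
        {c: getattr(r, c) for c in EA_RECORD_COLUMNS} for r in records
    ]
    return pd.DataFrame(rows, columns=EA_RECORD_COLUMNS)


def fisher_rao_phase_distance(g: Warping) -> float:
    """Fisher-Rao distance of a warp from the identity.

    d_FR(gamma, id) = arccos( int_0^1 sqrt(gamma'(t)) dt ), a proper metric
    on the warping group, valued in [0, pi/2].  gamma' comes from the
    package's finite-difference scheme; the inner product is clamped to
    [-1, 1] before the arccos.
    """
    gd = np.clip(derivative(g.gamma, g.grid), 0.0, None)
    inner = float(trapezoid(np.sqrt(gd), g.grid))
    return float(np.arccos(np.clip(inner, -1.0, 1.0)))


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = np.std(u), np.std(v)
    if su <= 0 or sv <= 0:
        raise UndefinedCorrelationError("zero-variance curve in correlation")
    r = float(np.corrcoef(u, v)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def ea_correlation(x: RatingCurve, a_hat: RatingCurve) -> tuple[float, float]:
    """EA measure: Pearson r between target and (aligned) perceiver values,
    with its Fisher-z transform."""
    if x.n != a_hat.n or not np.allclose(x.grid, a_hat.grid):
        raise InvalidCurveError("ea_correlation requires a common grid")
    r = _pearson(x.values, a_hat.values)
    z = float(np.arctanh(np.clip(r, -_Z_CLAMP, _Z_CLAMP)))
    return r, z


def amplitude_distance(
    a: RatingCurve, a_hat: RatingCurve, squared: bool = False
) -> float:
    """L2 distance || a - a_hat || on the normalized domain (trapezoid).

    ``squared=True`` returns the squared distance instead; the plain L2
    distance is the default convention for the simulation metric D_a.
    """
    if a.n != a_hat.n or not np.allclose(a.grid, a_hat.grid):
        raise InvalidCurveError("amplitude_distance requires a common grid")
    d2 = float(trapezoid((a.values - a_hat.values) ** 2, a.grid))
    return d2 if squared else float(np.sqrt(d2))


def correlation_bias(
    true_latents: list[RatingCurve],
    estimates: list[RatingCurve],
    x: RatingCurve,
) -> float:
    """Mean over perceivers of corr(a_hat_i, x) - corr(a_i, x)."""
    if len(true_latents) != len(estimates):
        raise InvalidCurveError("latents and estimates must have equal length")
    diffs = [
        _pearson(est.values, x.values) - _pearson(a.values, x.values)
        for a, est in zip(true_latents, estimates)
    ]
    return float(np.mean(diffs))


@dataclass(frozen=True)
class MixedModelFit:
    """REML fit of the bias/discrimination/variability mixed model.

    For one perceiver rating J stimuli, the model is

        y_jk = (beta0 + u0_j) + (beta1 + u1_j) x_jk + eps_jk

    with random intercept u0_j, random slope u1_j and residual eps_jk per
    stimulus j.  ``beta0`` is the perceiver's mean bias, ``beta1`` their
    discrimination; the sd components capture between-stimulus variability
    and random noise.  ``d_bar_warp`` and ``d_bar_vertical`` are the two fit
    diagnostics: the mean Fisher-Rao warp amount over stimuli and the mean
    L2 distance between the aligned response and the fitted-value function.
    """

    beta0: float
    beta1: float
    sd_u0: float
    sd_u1: float
    sd_e: float
    se_beta0: float
    se_beta1: float
    blups: dict[str, tuple[float, float]]
    d_bar_warp: float
    d_bar_vertical: float
    singular: bool = False

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta1": self.beta1,
            "sd_u0": self.sd_u0,
            "sd_u1": self.sd_u1,
            "sd_e": self.sd_e,
            "se_beta0": self.se_beta0,
            "se_beta1": self.se_beta1,
            "blups": {k: list(v) for k, v in self.blups.items()},
            "d_bar_warp": self.d_bar_warp,
            "d_bar_vertical": self.d_bar_vertical,
            "singular": self.singular,
        }


def fit_bias_discrimination_model(
    stimuli: list[tuple[RatingCurve, RatingCurve]],
    warps: list[Warping] | None = None,
) -> MixedModelFit:
    """Fit the per-perceiver mixed model across stimuli by REML.

    Parameters
    ----------
    stimuli
        List of ``(x_j, y_aligned_j)`` pairs, one per stimulus, on matched
        grids.  Estimation delegates to standard REML machinery
        (statsmodels ``MixedLM`` with random intercept and slope grouped by
        stimulus).
    warps
        Optional estimated warps, one per stimulus, used for the
        ``d_bar_warp`` diagnostic; identity warp amount (0) is assumed when
        omitted.
    """
    import statsmodels.api as sm

    if len(stimuli) < 2:
        raise InvalidCurveError("mixed model needs at least 2 stimuli")
    frames = []
    for j, (xj, yj) in enumerate(stimuli):
        if xj.n != yj.n or not np.allclose(xj.grid, yj.grid):
            raise InvalidCurveError(f"stimulus {j}: grids do not match")
        frames.append(
            pd.DataFrame(
                {"stimulus": str(j), "x": xj.values, "y": yj.values}
            )
        )
    data = pd.concat(frames, ignore_index=True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            "y ~ x", groups="stimulus", re_formula="~x", data=data
        )
        fit = model.fit(reml=True)

    beta0 = float(fit.fe_params["Intercept"])
    beta1 = float(fit.fe_params["x"])
    cov_re = np.asarray(fit.cov_re)
    sd_u0 = float(np.sqrt(max(cov_re[0, 0], 0.0)))
    sd_u1 = float(np.sqrt(max(cov_re[1, 1], 0.0)))
    sd_e = float(np.sqrt(max(fit.scale, 0.0)))
    # a singular random-effect covariance is flagged, not fatal: BLUPs
    # degenerate to zero and the fixed effects remain usable
    singular = bool(not fit.converged
                    or np.linalg.eigvalsh(cov_re).min() < 1e-10)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            blups = {
                str(k): (float(v.iloc[0]), float(v.iloc[1]))
                for k, v in fit.random_effects.items()
            }
    except (ValueError, np.linalg.LinAlgError):
        singular = True
        blups = {str(j): (0.0, 0.0) for j in range(len(stimuli))}

    # fit diagnostics
    d_warps = (
        [fisher_rao_phase_distance(g) for g in warps]
        if warps is not None
        else [0.0] * len(stimuli)
    )
    d_vert = []
    for j, (xj, yj) in enumerate(stimuli):
        u0, u1 = blups[str(j)]
        fitted = (beta0 + u0) + (beta1 + u1) * xj.values
        d_vert.append(
            float(np.sqrt(trapezoid((yj.values - fitted) ** 2, xj.grid)))
        )

    return MixedModelFit(
        beta0=beta0,
        beta1=beta1,
        sd_u0=sd_u0,
        sd_u1=sd_u1,
        sd_e=sd_e,
        se_beta0=float(fit.bse_fe["Intercept"]),
        se_beta1=float(fit.bse_fe["x"]),
        blups=blups,
        d_bar_warp=float(np.mean(d_warps)),
        d_bar_vertical=float(np.mean(d_vert)),
        singular=singular,
    )
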