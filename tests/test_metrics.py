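"""EA metrics: phase distance, correlations, amplitude distance, mixed model."""

import numpy as np
import pytest

from ea_align import (
    AlignmentConfig,
    RatingCurve,
    Warping,
    align_pair,
    amplitude_distance,
    correlation_bias,
    ea_correlation,
    fisher_rao_phase_distance,
    fit_bias_discrimination_model,
    identity_warping,
    invert_warping,
    uniform_grid,
)
from ea_align.errors import UndefinedCorrelationError
from ea_align.simgen import generate_latent_sim1, make_synthetic_target, random_warp
from ea_align.align import apply_alignment


class TestFisherRaoPhaseDistance:
    def test_identity_has_zero_distance(self):
        assert fisher_rao_phase_distance(identity_warping(uniform_grid(100))) == 0.0

    def test_quadratic_warp_closed_form(self):
        t = uniform_grid(2001)
        d = fisher_rao_phase_distance(Warping(t, t**2))
        assert d == pytest.approx(np.arccos(2 * np.sqrt(2) / 3), abs=1e-3)

    def test_distance_invariant_under_inversion(self):
        # change of variables gives d_FR(gamma) = d_FR(gamma^{-1}); use
        # warps with slopes bounded away from 0 so quadrature error stays
        # below the tolerance
        t = uniform_grid(2001)
        for g in (
            Warping(t, t + 0.2 * np.sin(np.pi * t)),
            Warping(t, np.expm1(2 * t) / np.expm1(2)),
        ):
            assert fisher_rao_phase_distance(g) == pytest.approx(
                fisher_rao_phase_distance(invert_warping(g)), abs=1e-3
            )

    def test_zero_iff_identity(self):
        t = uniform_grid(500)
        g = Warping(t, 0.9 * t + 0.1 * t**2)
        assert fisher_rao_phase_distance(g) > 1e-4
        assert g.sup_dev > 1e-3


class TestEaCorrelation:
    def test_affine_invariance(self):
        t = uniform_grid(100)
        x = RatingCurve(t, np.sin(2 * np.pi * t) + 5)
        r, z = ea_correlation(x, x.with_values(2 * x.values + 1))
        assert r == pytest.approx(1.0)
        assert np.isfinite(z)

    def test_residualized_noise_is_uncorrelated(self, rng):
        t = uniform_grid(300)
        xv = np.sin(2 * np.pi * t) + 5
        noise = rng.normal(size=300)
        xc = xv - xv.mean()
        resid = noise - (noise @ xc) / (xc @ xc) * xc
        x = RatingCurve(t, xv)
        r, _ = ea_correlation(x, x.with_values(resid + 5))
        assert abs(r) <= 0.05

    def test_fisher_z_closed_form(self):
        t = uniform_grid(4)
        # construct r = 0.5 directly through the formula instead
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)
        x = RatingCurve(t, np.array([0.0, 1.0, 2.0, 3.0]))
        r, z = ea_correlation(x, x.with_values(x.values))
        assert z == np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))

    def test_zero_variance_raises(self):
        t = uniform_grid(10)
        x = RatingCurve(t, np.sin(t) + 2)
        with pytest.raises(UndefinedCorrelationError):
            ea_correlation(x, x.with_values(np.full(10, 3.0)))


class TestAmplitudeDistance:
    def test_zero_for_equal_curves(self):
        t = uniform_grid(50)
        a = RatingCurve(t, np.sin(t))
        assert amplitude_distance(a, a) == 0.0

    def test_constant_offset_closed_form(self):
        t = uniform_grid(100)
        a = RatingCurve(t, np.sin(t))
        assert amplitude_distance(a, a.with_values(a.values + 2.5)) == \
            pytest.approx(2.5, abs=1e-12)

    def test_matches_closed_form_quadrature(self):
        t = uniform_grid(2001)
        a = RatingCurve(t, np.sin(2 * np.pi * t))
        b = RatingCurve(t, np.zeros(2001))
        # ||sin(2 pi t)|| = sqrt(1/2)
        assert amplitude_distance(a, b) == pytest.approx(
            np.sqrt(0.5), rel=1e-6
        )

    def test_triangle_inequality(self, rng):
        t = uniform_grid(101)
        for _ in range(20):
            a, b, c = (RatingCurve(t, rng.normal(size=101)) for _ in range(3))
            assert amplitude_distance(a, c) <= (
                amplitude_distance(a, b) + amplitude_distance(b, c) + 1e-9
            )


class TestCorrelationBias:
    def make_batch(self, rng):
        t = uniform_grid(120)
        x = RatingCurve(t, np.sin(2 * np.pi * t) + 5)
        latents = [
            x.with_values(x.values + rng.normal(0, 0.8, 120)) for _ in range(3)
        ]
        return x, latents

    def test_zero_when_estimates_equal_truth(self, rng):
        x, latents = self.make_batch(rng)
        assert correlation_bias(latents, latents, x) == 0.0

    def test_perfect_overalignment_bound(self, rng):
        x, latents = self.make_batch(rng)
        estimates = [x.with_values(x.values.copy()) for _ in latents]
        expected = np.mean(
            [1.0 - np.corrcoef(a.values, x.values)[0, 1] for a in latents]
        )
        assert correlation_bias(latents, estimates, x) == pytest.approx(expected)

    def test_matches_direct_two_pass_computation(self, rng):
        x, latents = self.make_batch(rng)
        estimates = [
            x.with_values(a.values + rng.normal(0, 0.2, 120)) for a in latents
        ]
        direct = np.mean(
            [
                np.corrcoef(e.values, x.values)[0, 1]
                - np.corrcoef(a.values, x.values)[0, 1]
                for a, e in zip(latents, estimates)
            ]
        )
        assert correlation_bias(latents, estimates, x) == pytest.approx(
            direct, abs=1e-12
        )


class TestMixedModel:
    def test_identity_relation_recovered(self):
        rng = np.random.default_rng(3)
        t = uniform_grid(80)
        stimuli = []
        for _ in range(3):
            x = RatingCurve(t, 5 + np.cumsum(rng.normal(0, 0.2, 80)))
            stimuli.append((x, x.with_values(x.values.copy())))
        fit = fit_bias_discrimination_model(stimuli)
        assert fit.beta0 == pytest.approx(0.0, abs=1e-6)
        assert fit.beta1 == pytest.approx(1.0, abs=1e-6)
        assert fit.sd_e == pytest.approx(0.0, abs=1e-6)
        assert fit.d_bar_warp == 0.0
        assert len(fit.blups) == 3

    def test_singular_fit_is_flagged_not_fatal(self):
        rng = np.random.default_rng(4)
        t = uniform_grid(50)
        stimuli = []
        for _ in range(2):
            x = RatingCurve(t, 5 + np.cumsum(rng.normal(0, 0.2, 50)))
            stimuli.append((x, x.with_values(x.values.copy())))
        fit = fit_bias_discrimination_model(stimuli)
        assert fit.singular


class TestShrinkageOrdering:
    def test_constrained_warps_are_closer_to_identity(self):
        """Across a batch of noisy pairs the constrained aligner warps less
        (smaller mean Fisher-Rao phase distance) than the unconstrained one."""
        d_sup, d_unpen = [], []
        for seed in range(8):
            x = make_synthetic_target("high_positive", 150, seed=seed)
            a = generate_latent_sim1(x, (0.8, 0.8), 0.02, seed=seed + 100)
            g = random_warp(4.0, 108.0, 150, seed=seed + 200)
            y = apply_alignment(a, g)
            sup = align_pair(
                x, y,
                AlignmentConfig(method="srvf_sup_penalized", delta_seconds=4.0),
            )
            unpen = align_pair(x, y, AlignmentConfig(method="srvf_unpenalized"))
            d_sup.append(sup.phase_distance)
            d_unpen.append(unpen.phase_distance)
        assert np.mean(d_sup) <= np.mean(d_unpen)
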