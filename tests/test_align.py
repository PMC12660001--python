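"""The DP aligner: brute-force equivalence, limit identities, recovery."""

import math

import numpy as np
import pytest

from ea_align import (
    AlignmentConfig,
    RatingCurve,
    Srvf,
    align_pair,
    apply_alignment,
    identity_warping,
    invert_warping,
    segment_cost,
    uniform_grid,
)
from ea_align.align import _dp_solve
from ea_align.errors import InvalidConfigError
from ea_align.simgen import make_synthetic_target, random_warp

from _bruteforce import exhaustive_minimum, monotone_paths, objective_on_grid
from conftest import random_srvf_pair


def small_pair(x_vals, y_vals, duration=108.0):
    t = uniform_grid(len(x_vals))
    return (
        RatingCurve(t, np.asarray(x_vals, float), duration),
        RatingCurve(t, np.asarray(y_vals, float), duration),
    )


class TestSegmentCost:
    def test_diagonal_segment_of_equal_srvfs_is_free(self, rng):
        qx, _ = random_srvf_pair(8, rng)
        assert segment_cost(qx, qx, (2, 2), (5, 5)) == pytest.approx(0.0, abs=1e-14)

    def test_zero_qy_reduces_to_qx_norm(self, rng):
        qx, _ = random_srvf_pair(8, rng)
        qy = Srvf(qx.grid, np.zeros(8))
        got = segment_cost(qx, qy, (1, 1), (5, 5))
        expected = np.trapezoid(qx.q[1:6] ** 2, qx.grid[1:6])
        assert got == pytest.approx(expected, abs=1e-14)

    def test_path_cost_is_additive(self, rng):
        """Segment costs summed along a path equal the directly discretized
        objective for that piecewise-linear warp."""
        qx, qy = random_srvf_pair(6, rng)
        for path in list(monotone_paths(6))[::7]:
            direct = objective_on_grid(qx.grid, qx.q, qy.q, path)
            summed = sum(
                segment_cost(qx, qy, path[s], path[s + 1])
                for s in range(len(path) - 1)
            )
            assert summed == pytest.approx(direct, abs=1e-10)


class TestDpOracle:
    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_dp_equals_bruteforce_minimum(self, n, rng):
        for _ in range(12):
            qx, qy = random_srvf_pair(n, rng)
            for delta, lam in [(np.inf, 0.0), (0.3, 0.0), (np.inf, 0.5)]:
                _, obj = _dp_solve(qx, qy, delta, lam, n - 1)
                best = exhaustive_minimum(qx.grid, qx.q, qy.q, delta, lam)
                assert obj == pytest.approx(best, abs=1e-10)


class TestLimitIdentities:
    def test_identical_curves_align_to_identity(self):
        t = uniform_grid(60)
        x = RatingCurve(t, np.sin(2 * np.pi * t) + 5, 108.0)
        res = align_pair(x, x, AlignmentConfig(method="srvf_unpenalized"))
        np.testing.assert_allclose(res.gamma_hat.gamma, t, atol=1e-12)
        assert res.objective == pytest.approx(0.0, abs=1e-12)

    def test_delta_zero_forces_identity(self, rng):
        x, y = small_pair(rng.normal(size=60), rng.normal(size=60))
        res = align_pair(
            x, y, AlignmentConfig(method="srvf_sup_penalized", delta_seconds=0.0)
        )
        np.testing.assert_allclose(res.gamma_hat.gamma, x.grid, atol=1e-12)
        np.testing.assert_allclose(res.aligned.values, y.values, atol=1e-12)

    def test_inactive_band_matches_unpenalized(self, rng):
        x, y = small_pair(rng.normal(size=60), rng.normal(size=60))
        unpen = align_pair(x, y, AlignmentConfig(method="srvf_unpenalized"))
        wide = align_pair(
            x, y,
            AlignmentConfig(method="srvf_sup_penalized", delta_seconds=108.0),
        )
        np.testing.assert_allclose(
            wide.gamma_hat.gamma, unpen.gamma_hat.gamma, atol=1e-12
        )
        assert wide.objective == pytest.approx(unpen.objective, abs=1e-12)

    def test_lambda_zero_matches_unpenalized(self, rng):
        x, y = small_pair(rng.normal(size=60), rng.normal(size=60))
        unpen = align_pair(x, y, AlignmentConfig(method="srvf_unpenalized"))
        pen0 = align_pair(
            x, y, AlignmentConfig(method="srvf_l2_penalized", lambda_penalty=0.0)
        )
        np.testing.assert_allclose(
            pen0.gamma_hat.gamma, unpen.gamma_hat.gamma, atol=1e-12
        )

    def test_huge_lambda_shrinks_to_identity(self, rng):
        n = 60
        x, y = small_pair(rng.normal(size=n), rng.normal(size=n))
        res = align_pair(
            x, y, AlignmentConfig(method="srvf_l2_penalized", lambda_penalty=1e6)
        )
        assert np.max(np.abs(res.gamma_hat.gamma - x.grid)) <= 2.0 / n

    def test_objective_monotone_in_delta(self, rng):
        x, y = small_pair(rng.normal(size=50), rng.normal(size=50))
        deltas = [0.0, 2.0, 5.0, 10.0, 30.0, 108.0]
        objs = [
            align_pair(
                x, y,
                AlignmentConfig(method="srvf_sup_penalized", delta_seconds=d),
            ).objective
            for d in deltas
        ]
        assert all(a >= b - 1e-12 for a, b in zip(objs, objs[1:]))

    def test_band_feasibility_always_holds(self, rng):
        for d in (1.0, 3.0, 7.0):
            x, y = small_pair(rng.normal(size=80), rng.normal(size=80))
            res = align_pair(
                x, y,
                AlignmentConfig(method="srvf_sup_penalized", delta_seconds=d),
            )
            assert res.feasible
            assert res.gamma_hat.sup_dev * 108.0 <= d + 1e-9


class TestFixedDelay:
    def make_target(self):
        # 2-second epochs over 108 s
        t_sec = np.arange(0, 110, 2.0)
        vals = 5 + 2 * np.sin(2 * np.pi * t_sec / 40) + np.cos(2 * np.pi * t_sec / 15)
        t = t_sec / 108.0
        return RatingCurve(t / t[-1], vals, 108.0)

    def test_no_shift_for_identical_curves(self):
        x = self.make_target()
        res = align_pair(x, x, AlignmentConfig(method="fixed_delay"))
        np.testing.assert_allclose(res.gamma_hat.gamma, x.grid, atol=1e-12)

    def test_recovers_a_three_second_delay(self):
        x = self.make_target()
        shifted = np.interp(
            x.grid * 108.0 - 3.0, x.grid * 108.0, x.values
        )  # clamped by np.interp at the ends
        y = x.with_values(shifted)
        res = align_pair(
            x, y, AlignmentConfig(method="fixed_delay", max_delay_seconds=10.0)
        )
        # the perceiver lags by 3 s, so the aligner advances it by a
        # grid-adjacent amount (grid step is 2 s)
        shift_sec = abs((x.grid - res.gamma_hat.gamma)[x.n // 2]) * 108.0
        assert shift_sec == pytest.approx(2.0, abs=1e-9) or \
            shift_sec == pytest.approx(4.0, abs=1e-9)
        at_zero = np.trapezoid((x.values - y.values) ** 2, x.grid)
        assert res.objective <= at_zero + 1e-12

    def test_overlong_max_delay_rejected(self):
        x = self.make_target()
        with pytest.raises(InvalidConfigError):
            align_pair(
                x, x,
                AlignmentConfig(method="fixed_delay", max_delay_seconds=200.0),
            )


class TestApplyAlignment:
    def test_identity_leaves_curve_unchanged(self, rng):
        t = uniform_grid(80)
        y = RatingCurve(t, rng.normal(size=80))
        out = apply_alignment(y, identity_warping(t))
        np.testing.assert_allclose(out.values, y.values, atol=1e-12)

    def test_inversion_round_trip(self):
        n = 400
        t = uniform_grid(n)
        y = RatingCurve(t, np.sin(2 * np.pi * t) + 5)
        from ea_align import Warping

        g = Warping(t, t**1.3)
        back = apply_alignment(apply_alignment(y, g), invert_warping(g))
        rng_y = y.values.max() - y.values.min()
        assert np.max(np.abs(back.values - y.values)) <= 2 * rng_y / n

    def test_endpoints_preserved(self, rng):
        t = uniform_grid(50)
        y = RatingCurve(t, rng.normal(size=50))
        from ea_align import Warping

        g = Warping(t, t**2)
        out = apply_alignment(y, g)
        assert out.values[0] == y.values[0]
        assert out.values[-1] == y.values[-1]


class TestRecovery:
    def test_known_warp_is_undone(self):
        """y = a o gamma with a 4-s sup-norm warp; aligning y back to a at
        delta = 6 s recovers the latent curve almost perfectly."""
        a = make_synthetic_target("low_positive", 300, seed=3)
        g = random_warp(4.0, 108.0, 300, seed=5)
        y = apply_alignment(a, g).with_values(
            np.interp(g.gamma, a.grid, a.values)
        )
        res = align_pair(
            a, y, AlignmentConfig(method="srvf_sup_penalized", delta_seconds=6.0)
        )
        r = np.corrcoef(res.aligned.values, a.values)[0, 1]
        assert r >= 0.99
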