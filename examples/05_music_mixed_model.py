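"""Bias/discrimination/variability mixed model with an alignment step.

One perceiver rates J = 5 stimuli; their responses follow the mixed model
y = (b0 + u0_j) + (b1 + u1_j) x + noise, then get warped in time.  Fitting
after constrained alignment recovers the discrimination slope and shows a
smaller vertical (fit) distance than fitting the raw misaligned curves.
"""

import numpy as np

from ea_align import (
    AlignmentConfig,
    RatingCurve,
    align_pair,
    fit_bias_discrimination_model,
    generate_observed,
    random_warp,
    uniform_grid,
)

rng = np.random.default_rng(5)
t = uniform_grid(150)
beta0, beta1 = 0.5, 0.9
pairs = []
for j in range(5):
    xv = 5 + np.cumsum(rng.normal(0, 0.3, 150))
    xv = 1 + 7 * (xv - xv.min()) / np.ptp(xv)
    x = RatingCurve(t, xv, 108.0)
    u0, u1 = rng.normal(0, 0.3), rng.normal(0, 0.05)
    latent = x.with_values(beta0 + u0 + (beta1 + u1) * xv
                           + rng.normal(0, 0.3, 150))
    g = random_warp(5.0, 108.0, 150, seed=50 + j)
    pairs.append((x, generate_observed(latent, g)))

for method in ("none", "srvf_sup_penalized"):
    cfg = AlignmentConfig(method=method, delta_seconds=6.0)
    stimuli, warps = [], []
    for x, y in pairs:
        res = align_pair(x, y, cfg)
        stimuli.append((x, res.aligned))
        warps.append(res.gamma_hat)
    fit = fit_bias_discrimination_model(stimuli, warps)
    print(f"{method:>20}: discrimination b1 = {fit.beta1:.3f}, "
          f"sd_e = {fit.sd_e:.3f}, d_bar_warp = {fit.d_bar_warp:.3f}, "
          f"d_bar_vertical = {fit.d_bar_vertical:.3f}")
print(f"(true discrimination b1 = {beta1})")
# Alignment should lower the vertical fit distance and move the
# discrimination estimate toward its true value.
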