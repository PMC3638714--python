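"""Landmark-noise robustness: shape-prior fit vs unconstrained LDDMM.

Reruns the simulated design at three landmark-noise levels (0.1x, 1x,
100x the voxel-derived base variance) over the 5 sampled shapes and
prints mean +/- sd of the kappa overlap for both methods.  At high noise
the exact-matching baseline overfits and collapses; the prior-
constrained fit degrades gracefully.
"""

from gdas.evaluate import robustness_report
from gdas.optimize import GDASConfig
from gdas.synthetic import SyntheticScenario

data = SyntheticScenario().build()
config = GDASConfig(sigma2=data.scenario.base_variance, step_size=0.05,
                    max_iter=150, tol=1e-8)
df = robustness_report(data, noise_multipliers=(0.1, 1.0, 100.0),
                       config=config, seed=0)

summary = df.groupby("noise_multiplier")[["kappa_gdas", "kappa_lddmm"]].agg(
    ["mean", "std"]
)
print(summary.round(3))
print()
print(df.groupby("noise_multiplier")["mahalanobis_error"].mean().round(2))
# kappa_gdas stays high and tight across noise levels; kappa_lddmm drops
# precipitously at 100x noise.  The last table is the mean Mahalanobis
# error of the recovered coefficients (sd units), growing with noise.
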