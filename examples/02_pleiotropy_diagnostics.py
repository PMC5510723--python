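"""See how the estimators separate under directional pleiotropy.

Every variant here has a direct +0.02 effect on the outcome that bypasses
the exposure (directional pleiotropy, InSIDE holding). The IVW estimate
absorbs that bias; MR-Egger attributes it to its intercept and keeps an
unbiased slope; the weighted median is dragged because *all* variants are
invalid. The all-methods table makes the comparison in one call.
"""

import numpy as np

from mrsummary import BootstrapConfig, SimulationConfig, mr_all, simulate_summary_data

rng = np.random.default_rng(4)
config = SimulationConfig(
    n_variants=30,
    theta=0.2,                      # true causal effect
    gamma=rng.uniform(0.1, 0.4, 30),
    pleiotropy_mode="directional",  # alpha_j ~ N(0.02, 0.01^2), independent of gamma
    pleiotropy_mean=0.02,
    pleiotropy_sd=0.01,
)
truth = simulate_summary_data(config, bxse=0.004, byse=0.008, rng=rng)

table = mr_all(truth.data, selection="all", bootstrap=BootstrapConfig(seed=4))
print(table)
print()
print(f"True causal effect: {truth.theta}; true mean pleiotropy: "
      f"{truth.alpha.mean():.4f}")
print("IVW overshoots theta by roughly mean(alpha)/mean(gamma); the MR-Egger")
print("slope is close to 0.2 and its (intercept) row is close to 0.02.")
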