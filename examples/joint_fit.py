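"""Simultaneous (joint-specification) fit of both submodels.

The JS posterior conditions the random effects on the survival outcome as
well, so no plug-in approximation is involved; it is the reference the
two-stage strategies are judged against, at a higher computational price.
"""

from twostagejm import (
    McmcConfig,
    SimulationConfig,
    default_priors,
    default_truth,
    fit_joint_js,
    simulate_dataset,
)

truth = default_truth()
data = simulate_dataset(SimulationConfig(truth=truth, n=200, seed=42))
summary = fit_joint_js(data, default_priors(), McmcConfig(seed=4))

print(summary.table.round(3))
print(f"\nmax rhat {summary.max_rhat:.3f} (converged: {summary.converged})")
print(f"true alpha = {truth.alpha}, true gamma1 = {truth.gamma[1]}")
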