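# Methods

## Model

One longitudinal marker per subject, linear in time with random intercept
and slope (K = 2), a single binary baseline covariate shared by both
submodels, and a proportional-hazards event model with exponential baseline
`h0(t) = exp(gamma0)` linked to the longitudinal process through the current
trajectory value (current-value association).  Substituting the linear
trajectory into the hazard makes the log-hazard affine in time,
`h_i(t) = w_i exp(c_i + d_i t)` with

```
c_i = gamma0 + gamma1 x_i + alpha (beta0 + b_0i + beta2 x_i)
d_i = alpha (beta1 + b_1i),
```

so `H_i(t) = w_i e^{c_i} (e^{d_i t} - 1)/d_i` in closed form.  The code is
specialised to this canonical model; the general mixed-model/hazard
formulation is documentation-level only, since every study result uses the
canonical form.  Setting `w_i = 1` reproduces the uncorrected hazard through
the identical code path.

Numerical choice: for `|d| < 1e-10` per unit time the cumulative hazard
switches to the exact limit `w e^c t`, because `expm1(d t)/d` loses accuracy
as `d -> 0`; the property suite checks continuity across the threshold at
1e-8 relative tolerance.

## Priors

Normal(0, sd^2) with sd = 100 on `beta`, `gamma`, `alpha` (the diffuse scale
is a package choice; 10 and 1000 behave equivalently in the sensitivity
tests except where a block is unidentified, see below); half-Cauchy(0, 5) on
`sigma`, represented internally by its inverse-gamma scale mixture so the
update is conjugate; inverse-Wishart(I, K) on `Sigma`; and, for the
corrected two-stage fit only, `w_i ~ Gamma(eta, eta)` with `eta` a fixed,
known constant (default 1.5, prior variance 1/1.5 ~ 0.67).  Treating `eta`
as unknown would turn the correction into a frailty model, which is
deliberately out of scope.

## Estimation strategies and samplers

The three estimators are properties of posteriors, not of any particular
sampler; the package uses the lightest sampler that is exact for each block
and requires split-Rhat < 1.05 (2 chains) on the core parameters of every
released fit, with one automatic retry at doubled iterations inside the
study harness.

* **Stage 1 / longitudinal.**  Fully conjugate Gibbs.  `beta` is drawn with
  the random effects integrated out (Woodbury on sigma^2 I + Z Sigma Z'),
  then `b | beta` from batched 2x2 Gaussian conditionals — the collapsed
  block removes the slow mixing between the fixed intercept and the mean of
  the random intercepts.  `sigma^2`, its half-Cauchy auxiliary, and `Sigma`
  are exact conjugate updates.
* **STS survival stage.**  Coordinate-wise slice sampling (stepping-out) of
  `(gamma0, gamma1, alpha)` in a centred parameterisation: the sampled
  intercept is `u0 = gamma0 + gamma1 xbar + alpha abar`, which removes the
  near-collinearity between `gamma0` and `alpha` that arises because the
  plug-in trajectory intercepts cluster far from zero (around 4.3 on the
  default scale).
* **NTS survival stage.**  As STS, plus an exact Gibbs draw of the
  multipliers: `w_i | gamma, alpha ~ Gamma(eta + delta_i, eta + H_i(T_i))`.
  The multipliers can also be integrated out analytically (Gamma mixing);
  the test suite uses that closed-form marginal, sampled with an independent
  ensemble sampler, as an oracle for the augmented chain.
* **JS.**  Metropolis-within-Gibbs.  Conjugate blocks as in stage 1; `b_i`
  and `beta` are proposed from their *longitudinal* Gaussian full
  conditionals and accepted with the survival-likelihood ratio (independence
  Metropolis — the proposal carries all longitudinal information, so
  acceptance is high); an exact interweaving move shifts
  `(beta0, beta1, beta2)` and counter-shifts every `b_i` along directions
  that leave all trajectories — hence both likelihoods — invariant, with a
  3-dim Gaussian conditional under the priors; the survival block is slice
  sampled as above.

MCMC sizing follows the standard protocol: 2000 iterations per chain with
1000 warm-up for the joint fit and the longitudinal stage, 1000/500 for the
plug-in survival stages, 2 chains throughout; all overridable via
`McmcConfig`.  The plug-in uses posterior means, never medians — discarding
stage-1 uncertainty is precisely what the two-stage estimators do.

## Simulator

Per subject: `x ~ Bernoulli(0.5)`; `b ~ N(0, Sigma)`; latent event time by
inverting `S(T) = u` in closed form (when `d < 0` the hazard can integrate
to a finite total, in which case the event never occurs and the subject is
censored with certainty); censoring `C ~ U(0, t_max)`; observed time
`T = min(T*, C)`; `m_min + floor(T)` equispaced measurements on `[0, T]`
inclusive (for the measure-zero case of an exactly integer `T`, the strict
"largest integer below T" reading is used); Gaussian noise around the
trajectory.  Defaults: truth from a joint fit to a randomised prednisone
trial in liver-cirrhosis patients (`beta = (4.274, -0.004, -0.097)`,
`sigma = 0.262`, `Sigma11 = 0.094`, `Sigma22 = 0.005`, `Sigma12 = -0.001`,
`gamma = (8.671, -0.172)`, `alpha = -2.447`), `m_min = 3`, `t_max = 15`,
giving an event rate around 2/3.

One master seed spawns named substreams (covariates, random effects, event
uniforms, censoring, noise), so changing `n` or `sigma` never shifts draws
in an unrelated stream and datasets are byte-identical under a fixed seed.

What the generator does *not* emulate: informative or covariate-dependent
censoring, visit processes tied to health status, nonlinear trajectories,
multiple markers, or measurement schedules that stop strictly before the
event.  Passing tests therefore demonstrate estimator behaviour under a
correctly specified joint model, not robustness to real-world deviations
from it.

## Study harness

Replicate seeds are `SeedSequence(master_seed, spawn_key=(n, rep))`, so any
cell regenerates in isolation and the report is invariant to execution
order; non-converged fits (after the one retry) are excluded from
aggregates but counted.  "SD" in the comparison table is the average
posterior SD across replicates (the SD of posterior means is reported
alongside).  The eta sensitivity mode reuses the same dataset seeds for
every eta, so differences are attributable to eta alone.

Problem sizes: the package's standard check profile uses 24 replicates at
n = 200 (all three methods) and 20 replicates at n = 1000 (two-stage
methods), which keeps cell Monte-Carlo SEs near 0.07 and 0.04 for `alpha`;
the full 100 x {200, 500, 1000} x 3 protocol runs through the same
`StudyConfig` defaults as a long batch mode.

## Known limitations

* The corrected two-stage posterior depends on `eta` by design; the default
  1.5 is calibrated to the scale of the canonical scenario and is not
  transferable to markers on other scales.
* With (nearly) no observed events the survival block is unidentified under
  very diffuse priors and the joint sampler mixes poorly there; the
  no-event consistency test uses a moderately diffuse prior (sd = 10) for
  that reason.
* Posterior means of weakly identified variance components (notably the
  random-slope variance) are prior-dominated under inverse-Wishart(I, K) at
  these sample sizes; this is a property of the model specification, shared
  by all three estimators.
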