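# twostagejm

Bayesian joint models of longitudinal and survival data, with three
estimation strategies:

* **JS** — the full joint specification, fitted simultaneously;
* **STS** — the standard two-stage plug-in (fit the longitudinal model,
  freeze its posterior-mean trajectories, fit the survival model);
* **NTS** — a bias-corrected two-stage fit that perturbs each subject's
  plug-in hazard with a multiplicative individual effect under an
  informative Gamma prior.

The package also ships the exact joint-data simulator and a replication
harness for the simulation study that compares the three strategies.

## The model

For subject *i* with binary group indicator *x\_i*, the longitudinal marker
follows a linear mixed model

```
y_i(t) = mu_i(t) + eps,   mu_i(t) = (beta0 + b_0i) + (beta1 + b_1i) t + beta2 x_i,
b_i ~ N(0, Sigma),        eps ~ N(0, sigma^2),
```

and the hazard of the terminal event is proportional-hazards with an
exponential baseline and the *current trajectory value* as a time-varying
covariate:

```
h_i(t) = exp(gamma0 + gamma1 x_i + alpha mu_i(t)).
```

Because `mu_i(t)` is linear in `t`, the log-hazard is linear in `t` and the
cumulative hazard, survival function and its inverse all have closed forms —
the simulator draws event times by exact inverse-transform sampling and
every fitter evaluates the survival likelihood without quadrature.

The association parameter `alpha` is the quantity of interest.  Plugging in
stage-1 posterior means (`beta_hat = E(beta|y)`, `b_hat = E(b|y)`) discards
the stage-1 uncertainty and attenuates `alpha` toward zero.  The corrected
two-stage fit replaces the hazard by

```
h_i(t) = w_i exp(gamma0 + gamma1 x_i + alpha mu_hat_i(t)),   w_i ~ Gamma(eta, eta),
```

where `E(w_i) = 1`, `Var(w_i) = 1/eta`, and `eta` is a known constant
(default 1.5).  The multipliers absorb the per-subject plug-in error and
restore `alpha`, at the price of a somewhat wider posterior.

Priors: diffuse Normal(0, 100^2) on `beta`, `gamma`, `alpha`; half-Cauchy(0, 5)
on `sigma`; inverse-Wishart(I, K) on `Sigma`.  All posteriors are computed by
the package's own samplers (conjugate/collapsed Gibbs, slice sampling, and
Metropolis-within-Gibbs with interweaving for the joint fit); every fit
reports split-Rhat and ESS.

## Worked example

`examples/two_stage_fit.py` simulates one dataset of 200 subjects under the
default truth (parameters estimated from a prednisone trial in
liver-cirrhosis patients; true `alpha = -2.447`) and runs both two-stage
fits:

```
stage 1 (mixed model):
            mean     sd   q2.5  q97.5   rhat       ess
parameter
beta[0]    4.239  0.039  4.162  4.317  1.000  2055.018
beta[1]    0.008  0.013 -0.018  0.034  1.001  1650.629
beta[2]   -0.055  0.053 -0.159  0.055  1.000  2013.248
sigma      0.262  0.006  0.251  0.275  1.002  1277.392

true association alpha = -2.447
STS: alpha = -1.990 (sd 0.247)  <- attenuated
NTS: alpha = -2.513 (sd 0.340)  <- corrected, wider
```

The standard plug-in underestimates the association strength by ~0.45 on
this dataset; the Gamma-multiplier correction recovers it.  The other
examples cover the joint fit (`joint_fit.py`), a miniature replication study
(`small_study.py`), dataset inspection and file output
(`simulate_and_inspect.py`), and the `eta` sensitivity sweep
(`eta_sensitivity.py`).

A thin CLI exposes the same operations
(`twostagejm simulate / fit / study / sensitivity / report`).

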