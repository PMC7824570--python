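"""Joint specification (JS) fit: simultaneous posterior of both submodels.

The sampler is Metropolis-within-Gibbs.  Conjugate blocks (sigma^2 and its
half-Cauchy auxiliary, Sigma) are exact Gibbs.  The random effects b_i and
the fixed effects beta are proposed from their *longitudinal* Gaussian full
conditionals and accepted with the ratio of survival likelihoods only — an
independence Metropolis step whose proposal already carries all the
longitudinal information, so acceptance stays high and mixing is governed by
the (weak) per-subject survival information.  Two extra exact moves keep the
chain well mixed:

* an ancillarity-interweaving translation that shifts (beta0, beta1, beta2)
  and counter-shifts every b_i so all trajectories — hence both likelihoods —
  are unchanged; its conditional is Gaussian in the 3-dim shift and breaks
  the fixed-effect/random-effect-mean coupling;
* the survival block (gamma0, gamma1, alpha) is slice-sampled in the same
  centred parameterisation as the two-stage fitters, given the current
  subject trajectories.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..model_core import _cum_hazard_cd
from ..simulate import JointDataset
from ._data import PackedData, pack_dataset, sample_mvn2_from_precision
from ._slice import slice_sweep
from .config import McmcConfig
from .priors import PriorSpec
from .summaries import PosteriorSummary, summarize_draws

__all__ = ["fit_joint_js", "joint_log_density"]

_WIDTHS = np.array([0.5, 0.5, 0.5])


def _surv_ll_subjects(
    packed: PackedData,
    a: np.ndarray,
    s: np.ndarray,
    g0: float,
    g1: float,
    alpha: float,
) -> np.ndarray:
    """Per-subject survival log-likelihood for trajectories a_i + s_i t (w = 1)."""
    c = g0 + g1 * packed.x + alpha * a
    d = alpha * s
    H = _cum_hazard_cd(c, d, 1.0, packed.T)
    return packed.delta * (c + d * packed.T) - H


def _traj_coeffs(packed: PackedData, beta: np.ndarray, b: np.ndarray):
    a = beta[0] + b[:, 0] + beta[2] * packed.x
    s = beta[1] + b[:, 1]
    return a, s


def _update_b_mh(packed: PackedData, state: dict, rng: np.random.Generator) -> None:
    """Independence-MH update of every b_i from the longitudinal conditional."""
    sig2 = state["sig2"]
    beta = state["beta"]
    Sigma_inv = np.linalg.inv(state["Sigma"])
    Q = Sigma_inv[None, :, :] + packed.ZtZ / sig2
    v = (packed.Zty - np.einsum("nji,j->ni", packed.XtZ, beta)) / sig2
    prop, _ = sample_mvn2_from_precision(Q, v, rng)

    g0, g1, alpha = state["gamma0"], state["gamma1"], state["alpha"]
    a_cur, s_cur = _traj_coeffs(packed, beta, state["b"])
    a_new, s_new = _traj_coeffs(packed, beta, prop)
    ll_cur = _surv_ll_subjects(packed, a_cur, s_cur, g0, g1, alpha)
    ll_new = _surv_ll_subjects(packed, a_new, s_new, g0, g1, alpha)
    accept = np.log(rng.uniform(size=packed.n)) < (ll_new - ll_cur)
    state["b"][accept] = prop[accept]


def _update_beta_mh(
    packed: PackedData, state: dict, prior_sd: float, rng: np.random.Generator
) -> None:
    """Independence-MH update of beta from its longitudinal conditional given b."""
    sig2 = state["sig2"]
    b = state["b"]
    P = packed.XtX.sum(0) / sig2 + np.eye(3) / prior_sd**2
    m = (packed.Xty - np.einsum("nij,nj->ni", packed.XtZ, b)).sum(0) / sig2
    L = np.linalg.cholesky(P)
    mean = np.linalg.solve(P, m)
    prop = mean + np.linalg.solve(L.T, rng.standard_normal(3))

    g0, g1, alpha = state["gamma0"], state["gamma1"], state["alpha"]
    a_cur, s_cur = _traj_coeffs(packed, state["beta"], b)
    a_new, s_new = _traj_coeffs(packed, prop, b)
    ll_cur = float(np.sum(_surv_ll_subjects(packed, a_cur, s_cur, g0, g1, alpha)))
    ll_new = float(np.sum(_surv_ll_subjects(packed, a_new, s_new, g0, g1, alpha)))
    if np.log(rng.uniform()) < ll_new - ll_cur:
        state["beta"] = prop


def _interweave_translation(
    packed: PackedData, state: dict, prior_sd: float, rng: np.random.Generator
) -> None:
    """Exact Gibbs move beta += eps, b0i -= eps0 + eps2 x_i, b1i -= eps1.

    Every subject trajectory is invariant under this shift, so both
    likelihoods cancel and the conditional of eps under the beta and b priors
    is a 3-dim Gaussian.
    """
    P = np.linalg.inv(state["Sigma"])
    n = packed.n
    Sx = float(packed.x.sum())
    Q = np.array(
        [
            [n * P[0, 0], n * P[0, 1], Sx * P[0, 0]],
            [n * P[0, 1], n * P[1, 1], Sx * P[0, 1]],
            [Sx * P[0, 0], Sx * P[0, 1], Sx * P[0, 0]],
        ]
    ) + np.eye(3) / prior_sd**2
    Pb = state["b"] @ P.T  # (n, 2)
    lin = np.array(
        [Pb[:, 0].sum(), Pb[:, 1].sum(), float(Pb[packed.x == 1, 0].sum())]
    ) - state["beta"] / prior_sd**2
    L = np.linalg.cholesky(Q)
    mean = np.linalg.solve(Q, lin)
    eps = mean + np.linalg.solve(L.T, rng.standard_normal(3))
    state["beta"] = state["beta"] + eps
    state["b"][:, 0] -= eps[0] + eps[2] * packed.x
    state["b"][:, 1] -= eps[1]


def _update_survival_block(
    packed: PackedData, state: dict, prior_sd: float, rng: np.random.Generator
) -> None:
    a, s = _traj_coeffs(packed, state["beta"], state["b"])
    abar, xbar = float(a.mean()), float(packed.x.mean())
    var = prior_sd**2

    def logpost(p: np.ndarray) -> float:
        u0, g1, alpha = p
        g0 = u0 - g1 * xbar - alpha * abar
        ll = float(np.sum(_surv_ll_subjects(packed, a, s, g0, g1, alpha)))
        return ll - (g0**2 + g1**2 + alpha**2) / (2 * var)

    u0 = state["gamma0"] + state["gamma1"] * xbar + state["alpha"] * abar
    p = np.array([u0, state["gamma1"], state["alpha"]])
    p, _ = slice_sweep(p, logpost, _WIDTHS, rng)
    state["gamma1"], state["alpha"] = p[1], p[2]
    state["gamma0"] = p[0] - p[1] * xbar - p[2] * abar


def _update_sig2_sigma(
    packed: PackedData, state: dict, priors: PriorSpec, rng: np.random.Generator
) -> None:
    b, beta = state["b"], state["beta"]
    mu = (beta[0] + b[packed.idx, 0]) + (beta[1] + b[packed.idx, 1]) * packed.t \
        + beta[2] * packed.x[packed.idx]
    ssr = float(np.sum((packed.y - mu) ** 2))
    state["sig2"] = 1.0 / rng.gamma(0.5 + packed.n_obs / 2,
                                    1.0 / (1.0 / state["a_aux"] + ssr / 2))
    state["a_aux"] = 1.0 / rng.gamma(
        1.0, 1.0 / (1.0 / priors.cauchy_scale**2 + 1.0 / state["sig2"])
    )
    scale = priors.wishart_scale + b.T @ b
    state["Sigma"] = stats.invwishart.rvs(
        df=priors.wishart_df + packed.n, scale=scale, random_state=rng
    )


def fit_joint_js(
    data: JointDataset, priors: PriorSpec, mcmc: McmcConfig
) -> PosteriorSummary:
    """Simultaneous posterior over (beta, sigma, Sigma, b, gamma, alpha)."""
    packed = pack_dataset(data)
    kept = mcmc.kept
    beta_d = np.empty((mcmc.chains, kept, 3))
    sigma_d = np.empty((mcmc.chains, kept))
    Sigma_d = np.empty((mcmc.chains, kept, 3))
    g_d = np.empty((mcmc.chains, kept, 3))
    b_sum = np.zeros((packed.n, 2))

    X = np.stack([np.ones_like(packed.t), packed.t, packed.x[packed.idx]], axis=1)
    beta_ols, *_ = np.linalg.lstsq(X, packed.y, rcond=None)
    sig2_init = max(float(np.var(packed.y - X @ beta_ols)), 1e-6)
    g0_init = float(np.log(max(packed.delta.sum(), 1.0) / packed.T.sum()))

    for chain in range(mcmc.chains):
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(mcmc.seed, spawn_key=(30 + chain,)))
        )
        state = {
            "beta": beta_ols + 0.1 * rng.standard_normal(3),
            "b": np.zeros((packed.n, 2)),
            "sig2": sig2_init * float(np.exp(0.2 * rng.standard_normal())),
            "a_aux": 1.0,
            "Sigma": np.eye(2) * 0.1,
            "gamma0": g0_init + 0.1 * rng.standard_normal(),
            "gamma1": 0.1 * rng.standard_normal(),
            "alpha": 0.1 * rng.standard_normal(),
        }
        for it in range(mcmc.iterations):
            _update_beta_mh(packed, state, priors.normal_sd, rng)
            _update_b_mh(packed, state, rng)
            _interweave_translation(packed, state, priors.normal_sd, rng)
            _update_sig2_sigma(packed, state, priors, rng)
            _update_survival_block(packed, state, priors.normal_sd, rng)
            k = it - mcmc.warmup
            if k >= 0:
                beta_d[chain, k] = state["beta"]
                sigma_d[chain, k] = np.sqrt(state["sig2"])
                S = state["Sigma"]
                Sigma_d[chain, k] = (S[0, 0], S[1, 1], S[0, 1])
                g_d[chain, k] = (state["gamma0"], state["gamma1"], state["alpha"])
                b_sum += state["b"]

    draws = {
        "beta": beta_d,
        "sigma": sigma_d,
        "Sigma": Sigma_d,
        "gamma0": g_d[:, :, 0],
        "gamma1": g_d[:, :, 1],
        "alpha": g_d[:, :, 2],
    }
    summary = summarize_draws(
        draws,
        core=["beta", "sigma", "Sigma", "gamma0", "gamma1", "alpha"],
        rhat_threshold=mcmc.rhat_threshold,
        method="JS",
    )
    summary.draws["b_hat"] = b_sum / (mcmc.chains * kept)
    return summary


def joint_log_density(
    data: JointDataset,
    beta: np.ndarray,
    b: np.ndarray,
    sigma: float,
    Sigma: np.ndarray,
    gamma: np.ndarray,
    alpha: float,
    priors: PriorSpec,
) -> float:
    """Unnormalised log joint density of the shared-parameter factorisation.

    Sum of the longitudinal Gaussian likelihood, the right-censored survival
    likelihood, the N(0, Sigma) random-effects density, and the prior
    log-densities (half-Cauchy marginal for sigma).  Used for consistency
    checks; the JS sampler targets exactly this density (with the
    half-Cauchy represented through its inverse-gamma scale mixture).
    """
    from ..model_core import (
        LinearHazard,
        log_lik_longitudinal,
        log_lik_survival,
        linear_hazard_coefficients,
        SurvivalParams,
        LongitudinalParams,
    )

    beta = np.asarray(beta, float)
    Sigma = np.asarray(Sigma, float)
    surv = SurvivalParams(gamma=np.asarray(gamma, float), alpha=float(alpha))
    lp = 0.0
    for i, rec in enumerate(data.subjects):
        lp += log_lik_longitudinal(rec, beta, b[i], sigma)
        lh = linear_hazard_coefficients(beta, b[i], surv, rec.x)
        lp += log_lik_survival(rec, lh)
        lp += float(stats.multivariate_normal.logpdf(b[i], mean=np.zeros(2), cov=Sigma))
    v = priors.normal_sd
    for val in (*beta, *surv.gamma, alpha):
        lp += float(stats.norm.logpdf(val, 0.0, v))
    lp += float(stats.halfcauchy.logpdf(sigma, 0.0, priors.cauchy_scale))
    lp += float(stats.invwishart.logpdf(Sigma, df=priors.wishart_df,
                                        scale=priors.wishart_scale))
    return lp
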