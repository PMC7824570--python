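"""Stage-1 fit: fully conjugate Gibbs sampler for the linear mixed model.

The sampler block-updates (beta, b) jointly — beta is drawn from its
conditional with the random effects integrated out (via Woodbury on the
per-subject marginal covariance sigma^2 I + Z Sigma Z'), then b given beta —
which removes the notorious slow mixing between the fixed intercept and the
random-intercept mean.  sigma^2 uses the half-Cauchy scale-mixture
representation (sigma^2 ~ IG(1/2, 1/a_aux), a_aux ~ IG(1/2, 1/scale^2)),
and Sigma its conjugate inverse-Wishart update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..simulate import JointDataset
from ._data import PackedData, pack_dataset, inv2x2, sample_mvn2_from_precision
from .config import McmcConfig
from .priors import PriorSpec
from .summaries import PosteriorSummary, summarize_draws

__all__ = ["StageOneEstimates", "fit_longitudinal"]


@dataclass
class StageOneEstimates:
    """Posterior means of the longitudinal fit, as plugged into stage 2.

    ``intercepts``/``slopes`` are the per-subject trajectory coefficients
    mu_hat_i(t) = intercepts[i] + slopes[i] t, i.e. beta0_hat + b0i_hat +
    beta2_hat x_i and beta1_hat + b1i_hat.
    """

    beta_hat: np.ndarray  # (3,)
    b_hat: np.ndarray  # (n, 2)
    intercepts: np.ndarray  # (n,)
    slopes: np.ndarray  # (n,)


def _init_state(packed: PackedData, rng: np.random.Generator) -> dict:
    X = np.stack([np.ones_like(packed.t), packed.t, packed.x[packed.idx]], axis=1)
    beta, *_ = np.linalg.lstsq(X, packed.y, rcond=None)
    resid = packed.y - X @ beta
    sig2 = max(float(np.var(resid)), 1e-6)
    return {
        "beta": beta + 0.1 * rng.standard_normal(3),
        "b": np.zeros((packed.n, 2)),
        "sig2": sig2 * float(np.exp(0.2 * rng.standard_normal())),
        "a_aux": 1.0,
        "Sigma": np.eye(2) * 0.1,
    }


def _update_beta_collapsed(
    packed: PackedData, state: dict, prior_sd: float, rng: np.random.Generator
) -> None:
    sig2 = state["sig2"]
    Sigma_inv = np.linalg.inv(state["Sigma"])
    A = Sigma_inv[None, :, :] + packed.ZtZ / sig2
    Ainv = inv2x2(A)
    XtZ_Ainv = np.einsum("nij,njk->nik", packed.XtZ, Ainv)
    XtVX = packed.XtX.sum(0) / sig2 - np.einsum(
        "nik,njk->ij", XtZ_Ainv, packed.XtZ
    ) / sig2**2
    XtVy = packed.Xty.sum(0) / sig2 - np.einsum(
        "nik,nk->i", XtZ_Ainv, packed.Zty
    ) / sig2**2
    P = XtVX + np.eye(3) / prior_sd**2
    L = np.linalg.cholesky(P)
    mean = np.linalg.solve(P, XtVy)
    state["beta"] = mean + np.linalg.solve(L.T, rng.standard_normal(3))


def _update_b(packed: PackedData, state: dict, rng: np.random.Generator) -> np.ndarray:
    """Draw b | beta, sigma^2, Sigma; returns the conditional means as well."""
    sig2 = state["sig2"]
    Sigma_inv = np.linalg.inv(state["Sigma"])
    Q = Sigma_inv[None, :, :] + packed.ZtZ / sig2
    v = (packed.Zty - np.einsum("nji,j->ni", packed.XtZ, state["beta"])) / sig2
    draw, _ = sample_mvn2_from_precision(Q, v, rng)
    state["b"] = draw
    return draw


def _update_sig2(
    packed: PackedData, state: dict, cauchy_scale: float, rng: np.random.Generator
) -> None:
    b = state["b"]
    beta = state["beta"]
    mu = (beta[0] + b[packed.idx, 0]) + (beta[1] + b[packed.idx, 1]) * packed.t \
        + beta[2] * packed.x[packed.idx]
    ssr = float(np.sum((packed.y - mu) ** 2))
    shape = 0.5 + packed.n_obs / 2
    rate = 1.0 / state["a_aux"] + ssr / 2
    state["sig2"] = 1.0 / rng.gamma(shape, 1.0 / rate)
    state["a_aux"] = 1.0 / rng.gamma(1.0, 1.0 / (1.0 / cauchy_scale**2 + 1.0 / state["sig2"]))


def _update_Sigma(state: dict, priors: PriorSpec, rng: np.random.Generator) -> None:
    b = state["b"]
    scale = priors.wishart_scale + b.T @ b
    df = priors.wishart_df + b.shape[0]
    state["Sigma"] = stats.invwishart.rvs(df=df, scale=scale, random_state=rng)


def fit_longitudinal(
    data: JointDataset, priors: PriorSpec, mcmc: McmcConfig
) -> tuple[PosteriorSummary, StageOneEstimates]:
    """Posterior of (beta, sigma, Sigma, b) for the linear mixed submodel."""
    packed = pack_dataset(data)
    if np.any(np.bincount(packed.idx, minlength=packed.n) < 1):
        raise ValueError("every subject needs at least one measurement")

    kept = mcmc.kept
    beta_d = np.empty((mcmc.chains, kept, 3))
    sigma_d = np.empty((mcmc.chains, kept))
    Sigma_d = np.empty((mcmc.chains, kept, 3))  # (S11, S22, S12)
    b_sum = np.zeros((packed.n, 2))

    for chain in range(mcmc.chains):
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(mcmc.seed, spawn_key=(10 + chain,)))
        )
        state = _init_state(packed, rng)
        for it in range(mcmc.iterations):
            _update_beta_collapsed(packed, state, priors.normal_sd, rng)
            _update_b(packed, state, rng)
            _update_Sigma(state, priors, rng)
            _update_sig2(packed, state, priors.cauchy_scale, rng)
            k = it - mcmc.warmup
            if k >= 0:
                beta_d[chain, k] = state["beta"]
                sigma_d[chain, k] = np.sqrt(state["sig2"])
                S = state["Sigma"]
                Sigma_d[chain, k] = (S[0, 0], S[1, 1], S[0, 1])
                b_sum += state["b"]

    b_hat = b_sum / (mcmc.chains * kept)
    draws = {
        "beta": beta_d,
        "sigma": sigma_d,
        "Sigma": Sigma_d,
    }
    summary = summarize_draws(
        draws, core=["beta", "sigma", "Sigma"], rhat_threshold=mcmc.rhat_threshold,
        method="longitudinal",
    )
    beta_hat = beta_d.reshape(-1, 3).mean(0)
    est = StageOneEstimates(
        beta_hat=beta_hat,
        b_hat=b_hat,
        intercepts=beta_hat[0] + b_hat[:, 0] + beta_hat[2] * packed.x,
        slopes=beta_hat[1] + b_hat[:, 1],
    )
    return summary, est
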