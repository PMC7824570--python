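"""Two-stage survival fitters: oracles, limits and the eta -> infinity bridge."""

import numpy as np
import pytest

from twostagejm import (
    JointParameters,
    LongitudinalParams,
    McmcConfig,
    SimulationConfig,
    SurvivalParams,
    default_priors,
    fit_longitudinal,
    fit_survival_nts,
    fit_survival_sts,
    simulate_dataset,
)


def _mc_tol(summary, name, factor=4.0, floor=0.02):
    """Monte-Carlo tolerance from the sampler's own ESS."""
    row = summary.table.loc[name]
    return max(factor * row["sd"] / np.sqrt(row["ess"]), floor)


def test_reduces_to_exponential_regression_with_null_association(priors):
    # data simulated with alpha = 0: the posterior of gamma0 must agree with
    # the closed-form exponential-MLE oracle log(events / exposure)
    truth = JointParameters(
        longitudinal=LongitudinalParams(
            beta=np.array([0.0, 0.0, 0.0]), sigma=0.3, Sigma=np.eye(2) * 1e-6
        ),
        survival=SurvivalParams(gamma=np.array([-0.7, 0.0]), alpha=0.0),
    )
    ds = simulate_dataset(SimulationConfig(truth=truth, n=400, seed=5))
    _, est = fit_longitudinal(ds, priors, McmcConfig(seed=1))
    summary = fit_survival_sts(ds, est, priors, McmcConfig.survival_stage(seed=2))
    events = sum(s.delta for s in ds.subjects)
    exposure = sum(s.T for s in ds.subjects)
    assert abs(summary.mean("gamma0") - np.log(events / exposure)) < 3 * summary.sd("gamma0")
    assert abs(summary.mean("alpha")) < 3 * summary.sd("alpha")


def test_reproducible_under_fixed_seed(small_dataset, stage1_small, priors):
    _, est = stage1_small
    a = fit_survival_sts(small_dataset, est, priors, McmcConfig.survival_stage(seed=3))
    b = fit_survival_sts(small_dataset, est, priors, McmcConfig.survival_stage(seed=3))
    assert a.table.equals(b.table)


def test_misaligned_stage1_rejected(small_dataset, medium_dataset, stage1_small, priors):
    _, est = stage1_small
    with pytest.raises(ValueError, match="aligned"):
        fit_survival_sts(medium_dataset, est, priors, McmcConfig.survival_stage(seed=0))


def test_sts_posterior_matches_emcee_oracle(small_dataset, stage1_small, priors):
    """Dual-route check: slice sampler vs an independent affine-invariant
    ensemble sampler on a log-posterior assembled from scratch in this test."""
    emcee = pytest.importorskip("emcee")
    _, est = stage1_small
    x = np.array([s.x for s in small_dataset.subjects], float)
    T = np.array([s.T for s in small_dataset.subjects], float)
    delta = np.array([s.delta for s in small_dataset.subjects], float)
    a, s = est.intercepts, est.slopes

    def logpost(p):
        g0, g1, al = p
        c = g0 + g1 * x + al * a
        d = al * s
        with np.errstate(over="ignore"):
            H = np.where(np.abs(d) < 1e-10, np.exp(c) * T, np.exp(c) * np.expm1(d * T) / np.where(np.abs(d) < 1e-10, 1.0, d))
        ll = np.sum(delta * (c + d * T) - H)
        return ll - (g0**2 + g1**2 + al**2) / (2 * 100.0**2)

    ndim, nwalkers = 3, 24
    rng = np.random.default_rng(0)
    p0 = np.array([np.log(delta.sum() / T.sum()), 0.0, 0.0]) + 0.05 * rng.standard_normal((nwalkers, ndim))
    sampler = emcee.EnsembleSampler(nwalkers, ndim, logpost)
    sampler.run_mcmc(p0, 3000, progress=False)
    chain = sampler.get_chain(discard=1000, flat=True)

    summary = fit_survival_sts(
        small_dataset, est, priors, McmcConfig(iterations=3000, warmup=1000, seed=4)
    )
    for j, name in enumerate(["gamma0", "gamma1", "alpha"]):
        tol = _mc_tol(summary, name) + 4 * chain[:, j].std() / np.sqrt(200.0)
        assert abs(summary.mean(name) - chain[:, j].mean()) < tol


class TestNts:
    def test_large_eta_matches_sts(self, small_dataset, stage1_small):
        # Var(w) = 1/eta -> 0 freezes every multiplier at 1
        _, est = stage1_small
        pr_sts = default_priors()
        pr_stiff = default_priors(eta=1e8)
        mcmc = McmcConfig(iterations=3000, warmup=1000, seed=6)
        sts = fit_survival_sts(small_dataset, est, pr_sts, mcmc)
        nts = fit_survival_nts(small_dataset, est, pr_stiff, mcmc)
        for name in ("gamma0", "gamma1", "alpha"):
            tol = _mc_tol(sts, name) + _mc_tol(nts, name)
            assert abs(sts.mean(name) - nts.mean(name)) < tol

    def test_w_posterior_means_stay_near_one(self, medium_dataset, stage1_medium, priors):
        _, est = stage1_medium
        nts = fit_survival_nts(medium_dataset, est, priors, McmcConfig.survival_stage(seed=7))
        w = nts.draws["w"]
        w_means = w.reshape(-1, w.shape[-1]).mean(0)
        inside = np.mean((w_means > 0.2) & (w_means < 3.0))
        assert inside > 0.95

    def test_eta_never_sampled(self, small_dataset, stage1_small, priors):
        _, est = stage1_small
        nts = fit_survival_nts(small_dataset, est, priors, McmcConfig.survival_stage(seed=8))
        assert "eta" not in nts.table.index
        assert "w" in nts.draws

    def test_nts_approaches_sts_as_eta_grows(self, small_dataset, stage1_small):
        _, est = stage1_small
        mcmc = McmcConfig(iterations=2000, warmup=800, seed=9)
        sts = fit_survival_sts(small_dataset, est, default_priors(), mcmc)
        ref = np.array([sts.mean("gamma1"), sts.mean("alpha")])
        dists, slacks = [], []
        for eta in (1.5, 10.0, 100.0, 1e4):
            nts = fit_survival_nts(small_dataset, est, default_priors(eta=eta), mcmc)
            v = np.array([nts.mean("gamma1"), nts.mean("alpha")])
            dists.append(np.linalg.norm(v - ref))
            slacks.append(_mc_tol(nts, "alpha") + _mc_tol(nts, "gamma1"))
        for k in range(len(dists) - 1):
            assert dists[k + 1] <= dists[k] + slacks[k] + slacks[k + 1]

    def test_matches_emcee_on_analytically_marginalised_posterior(
        self, small_dataset, stage1_small, priors
    ):
        """The Gamma multipliers integrate out in closed form (Gamma mixing),
        leaving a 3-dim marginal posterior an independent ensemble sampler can
        target directly; the augmented Gibbs chain must agree with it."""
        emcee = pytest.importorskip("emcee")
        from scipy.special import gammaln

        _, est = stage1_small
        x = np.array([s.x for s in small_dataset.subjects], float)
        T = np.array([s.T for s in small_dataset.subjects], float)
        delta = np.array([s.delta for s in small_dataset.subjects], float)
        a, s = est.intercepts, est.slopes
        eta = priors.eta

        def logpost(p):
            g0, g1, al = p
            c = g0 + g1 * x + al * a
            d = al * s
            dd = np.where(np.abs(d) < 1e-10, 1.0, d)
            H = np.where(np.abs(d) < 1e-10, np.exp(c) * T, np.exp(c) * np.expm1(dd * T) / dd)
            ll = np.sum(
                delta * (c + d * T) + eta * np.log(eta)
                + gammaln(eta + delta) - gammaln(eta)
                - (eta + delta) * np.log(eta + H)
            )
            return ll - (g0**2 + g1**2 + al**2) / (2 * 100.0**2)

        rng = np.random.default_rng(1)
        p0 = np.array([np.log(delta.sum() / T.sum()), 0, 0]) + 0.05 * rng.standard_normal((24, 3))
        sampler = emcee.EnsembleSampler(24, 3, logpost)
        sampler.run_mcmc(p0, 3000, progress=False)
        chain = sampler.get_chain(discard=1000, flat=True)

        nts = fit_survival_nts(
            small_dataset, est, priors, McmcConfig(iterations=3000, warmup=1000, seed=12)
        )
        for j, name in enumerate(["gamma0", "gamma1", "alpha"]):
            tol = _mc_tol(nts, name) + 4 * chain[:, j].std() / np.sqrt(200.0)
            assert abs(nts.mean(name) - chain[:, j].mean()) < tol

    def test_posterior_sd_of_alpha_exceeds_sts(self, medium_dataset, stage1_medium, priors):
        # the correction deliberately adds individual-level uncertainty
        _, est = stage1_medium
        mcmc = McmcConfig.survival_stage(seed=10)
        sts = fit_survival_sts(medium_dataset, est, priors, mcmc)
        nts = fit_survival_nts(medium_dataset, est, priors, mcmc)
        assert nts.sd("alpha") > sts.sd("alpha")
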