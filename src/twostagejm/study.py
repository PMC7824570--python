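"""Replication harness for the simulation study.

Runs the factorial experiment (replicate datasets x sample sizes x
estimation methods), aggregates posterior means and SDs per cell into the
standard comparison-table layout, computes bias metrics against the
simulation truth, and sweeps the Gamma concentration eta for the
sensitivity analysis.  Replicate seeds are derived from the master seed and
the cell coordinates, never sequentially, so any cell can be regenerated in
isolation and the report is invariant to execution order.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import JointParameters
from .simulate import SimulationConfig, simulate_dataset, default_truth
from .inference import (
    McmcConfig,
    PosteriorSummary,
    default_priors,
    fit_joint_js,
    fit_longitudinal,
    fit_survival_nts,
    fit_survival_sts,
)

__all__ = [
    "StudyConfig",
    "StudyReport",
    "replicate_seed",
    "run_study",
    "summarize_comparison_table",
    "bias_metrics",
    "eta_sensitivity",
    "plot_posterior_means",
]

_SURV_PARAMS = ("gamma0", "gamma1", "alpha")


@dataclass(frozen=True)
class StudyConfig:
    """Design of one simulation-study run."""

    truth: JointParameters = field(default_factory=default_truth)
    n_grid: tuple[int, ...] = (200, 500, 1000)
    n_datasets: int = 100
    m_min: int = 3
    t_max: float = 15.0
    methods: tuple[str, ...] = ("JS", "STS", "NTS")
    eta: float = 1.5
    eta_grid: tuple[float, ...] = ()
    master_seed: int = 0
    mcmc_long: McmcConfig = field(default_factory=lambda: McmcConfig())
    mcmc_surv: McmcConfig = field(default_factory=lambda: McmcConfig.survival_stage())
    normal_sd: float = 100.0

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if not self.n_grid or not self.methods:
            raise ValueError("n_grid and methods must be nonempty")
        bad = set(self.methods) - {"JS", "STS", "NTS"}
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")


@dataclass
class StudyReport:
    """Per-replicate posterior records plus the truth they were simulated from.

    ``records`` has one row per (method, n, replicate, parameter) with the
    posterior mean and SD of that fit, the replicate's dataset seed, and
    convergence diagnostics; every aggregate is recomputable from it.
    """

    records: pd.DataFrame
    truth: JointParameters
    config: StudyConfig | None = None

    def aggregates(self) -> pd.DataFrame:
        """Mean/SD of posterior means and mean posterior SD per cell."""
        ok = self.records[self.records["converged"]]
        g = ok.groupby(["method", "n", "parameter"])
        out = g.agg(
            mean_of_means=("post_mean", "mean"),
            sd_of_means=("post_mean", lambda v: v.std(ddof=1) if len(v) > 1 else np.nan),
            mean_post_sd=("post_sd", "mean"),
            n_converged=("post_mean", "size"),
        ).reset_index()
        totals = (
            self.records.groupby(["method", "n", "parameter"])["post_mean"]
            .size()
            .rename("n_total")
            .reset_index()
        )
        return out.merge(totals, on=["method", "n", "parameter"])


def replicate_seed(master_seed: int, n: int, rep: int) -> int:
    """Deterministic, cell-addressable dataset seed (below 2^31)."""
    return int(np.random.SeedSequence(master_seed, spawn_key=(n, rep)).generate_state(1)[0] >> 1)


def _fit_with_retry(fit, mcmc: McmcConfig):
    """Run a fitter; on a convergence failure retry once with doubled iterations."""
    summary = fit(mcmc)
    retried = False
    if not summary.converged:
        summary = fit(mcmc.with_doubled_iterations())
        retried = True
    return summary, retried


def _record_rows(
    summary: PosteriorSummary, method: str, n: int, rep: int, seed: int,
    retried: bool, wall: float, params: tuple[str, ...]
) -> list[dict]:
    rows = []
    for p in params:
        if p not in summary.table.index:
            continue
        rows.append(
            {
                "method": method,
                "n": n,
                "rep": rep,
                "seed": seed,
                "parameter": p,
                "post_mean": summary.mean(p),
                "post_sd": summary.sd(p),
                "max_rhat": summary.max_rhat,
                "converged": summary.converged,
                "retried": retried,
                "wall_time_s": wall,
            }
        )
    return rows


def _run_replicate(cfg: StudyConfig, n: int, rep: int, eta: float) -> list[dict]:
    seed = replicate_seed(cfg.master_seed, n, rep)
    data = simulate_dataset(
        SimulationConfig(truth=cfg.truth, n=n, m_min=cfg.m_min, t_max=cfg.t_max, seed=seed)
    )
    priors = default_priors(normal_sd=cfg.normal_sd, eta=eta)
    rows: list[dict] = []

    stage1 = None
    if {"STS", "NTS"} & set(cfg.methods):
        t0 = time.perf_counter()
        _, stage1 = fit_longitudinal(data, priors, replace(cfg.mcmc_long, seed=seed + 1))
        stage1_wall = time.perf_counter() - t0

    if "STS" in cfg.methods:
        t0 = time.perf_counter()
        summ, retried = _fit_with_retry(
            lambda m: fit_survival_sts(data, stage1, priors, m),
            replace(cfg.mcmc_surv, seed=seed + 2),
        )
        rows += _record_rows(summ, "STS", n, rep, seed, retried,
                             stage1_wall + time.perf_counter() - t0, _SURV_PARAMS)
    if "NTS" in cfg.methods:
        t0 = time.perf_counter()
        summ, retried = _fit_with_retry(
            lambda m: fit_survival_nts(data, stage1, priors, m),
            replace(cfg.mcmc_surv, seed=seed + 3),
        )
        rows += _record_rows(summ, "NTS", n, rep, seed, retried,
                             stage1_wall + time.perf_counter() - t0, _SURV_PARAMS)
    if "JS" in cfg.methods:
        t0 = time.perf_counter()
        summ, retried = _fit_with_retry(
            lambda m: fit_joint_js(data, priors, m), replace(cfg.mcmc_long, seed=seed + 4)
        )
        rows += _record_rows(
            summ, "JS", n, rep, seed, retried, time.perf_counter() - t0,
            _SURV_PARAMS + ("beta[0]", "beta[1]", "beta[2]", "sigma"),
        )
    return rows


def run_study(cfg: StudyConfig, checkpoint_dir: str | Path | None = None) -> StudyReport:
    """Run the full factorial experiment described by ``cfg``.

    With ``checkpoint_dir`` each completed (n, replicate) cell is written to
    disk as JSON and skipped on a rerun, so an interrupted study resumes
    where it stopped.
    """
    ckpt = Path(checkpoint_dir) if checkpoint_dir is not None else None
    if ckpt is not None:
        ckpt.mkdir(parents=True, exist_ok=True)
    all_rows: list[dict] = []
    for n in cfg.n_grid:
        for rep in range(cfg.n_datasets):
            if ckpt is not None:
                f = ckpt / f"cell_n{n}_rep{rep}.json"
                if f.exists():
                    all_rows += json.loads(f.read_text())
                    continue
            rows = _run_replicate(cfg, n, rep, cfg.eta)
            if ckpt is not None:
                f.write_text(json.dumps(rows))
            all_rows += rows
    return StudyReport(records=pd.DataFrame(all_rows), truth=cfg.truth, config=cfg)


def summarize_comparison_table(report: StudyReport) -> pd.DataFrame:
    """Comparison-table layout: {Mean, SD} x {gamma1, alpha}, columns method x n.

    "Mean" is the average of posterior means across replicate datasets and
    "SD" the average posterior SD, with the simulation truth printed beside
    the parameter label.  Cells absent from the report appear as NaN.
    """
    agg = report.aggregates()
    truth_vals = {"gamma1": report.truth.gamma[1], "alpha": report.truth.alpha}
    rows = []
    for stat, col in (("Mean", "mean_of_means"), ("SD", "mean_post_sd")):
        for param in ("gamma1", "alpha"):
            row: dict = {
                "posterior": stat,
                "parameter": f"{param} ({truth_vals[param]:.3f})",
            }
            for method in report.records["method"].unique():
                for n in sorted(report.records["n"].unique()):
                    cell = agg[
                        (agg["method"] == method)
                        & (agg["n"] == n)
                        & (agg["parameter"] == param)
                    ]
                    row[f"{method} n={n}"] = (
                        float(cell[col].iloc[0]) if len(cell) else np.nan
                    )
            rows.append(row)
    return pd.DataFrame(rows).set_index(["posterior", "parameter"])


def bias_metrics(report: StudyReport, truth: JointParameters | None = None) -> pd.DataFrame:
    """Bias of the mean posterior mean per cell, with its Monte-Carlo SE.

    relative bias = bias / |truth|; reported as NaN (undefined) when the true
    value is zero.
    """
    truth = truth if truth is not None else report.truth
    true_vals = {
        "gamma0": float(truth.gamma[0]),
        "gamma1": float(truth.gamma[1]),
        "alpha": float(truth.alpha),
        "beta[0]": float(truth.beta[0]),
        "beta[1]": float(truth.beta[1]),
        "beta[2]": float(truth.beta[2]),
        "sigma": float(truth.sigma),
    }
    agg = report.aggregates()
    agg = agg[agg["parameter"].isin(true_vals)].copy()
    agg["truth"] = agg["parameter"].map(true_vals)
    agg["bias"] = agg["mean_of_means"] - agg["truth"]
    agg["rel_bias"] = np.where(
        agg["truth"] == 0.0, np.nan, agg["bias"] / np.abs(agg["truth"])
    )
    agg["mc_se"] = agg["sd_of_means"] / np.sqrt(agg["n_converged"])
    return agg


def eta_sensitivity(cfg: StudyConfig) -> dict[float, StudyReport]:
    """One NTS study per eta on shared simulated datasets.

    Dataset seeds depend only on (master_seed, n, replicate), so every eta
    cell sees byte-identical data and differences are attributable to eta
    alone.
    """
    if not cfg.eta_grid:
        raise ValueError("eta_grid must be nonempty for a sensitivity run")
    if "NTS" not in cfg.methods:
        raise ValueError("sensitivity analysis requires the NTS method")
    out: dict[float, StudyReport] = {}
    for eta in cfg.eta_grid:
        sub = replace(cfg, methods=("NTS",), eta=eta, eta_grid=())
        out[eta] = run_study(sub)
    return out


def plot_posterior_means(report: StudyReport, parameter: str = "alpha"):
    """Strip plot of per-replicate posterior means by method and sample size,
    with a dashed line at the simulation truth."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    truth_vals = {"gamma1": report.truth.gamma[1], "alpha": report.truth.alpha}
    recs = report.records[report.records["parameter"] == parameter]
    ns = sorted(recs["n"].unique())
    methods = list(recs["method"].unique())
    fig, axes = plt.subplots(1, len(ns), figsize=(4 * len(ns), 4), sharey=True)
    axes = np.atleast_1d(axes)
    rng = np.random.default_rng(0)
    for ax, n in zip(axes, ns):
        for j, m in enumerate(methods):
            v = recs[(recs["n"] == n) & (recs["method"] == m)]["post_mean"]
            ax.scatter(j + 0.08 * rng.standard_normal(len(v)), v, s=12, alpha=0.6)
        ax.axhline(truth_vals.get(parameter, np.nan), ls="--", c="k", lw=1)
        ax.set_xticks(range(len(methods)), methods)
        ax.set_title(f"n = {n}")
    axes[0].set_ylabel(f"posterior mean of {parameter}")
    fig.tight_layout()
    return fig
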