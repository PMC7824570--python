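"""Posterior summaries and convergence diagnostics built on arviz."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PosteriorSummary", "summarize_draws"]


def _diagnostics(draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split-Rhat and bulk ESS for draws of shape (chains, kept[, dim])."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(draws[..., None] if draws.ndim == 2 else draws)
        rhat = np.atleast_1d(az.rhat(ds)["x"].values)
        ess = np.atleast_1d(az.ess(ds)["x"].values)
    return rhat, ess


@dataclass
class PosteriorSummary:
    """Per-parameter posterior mean/SD/95% interval plus rhat and ESS.

    ``table`` is indexed by parameter name; ``draws`` maps each named block
    to its (chains, kept_draws[, dim]) array so downstream consumers can
    recompute anything.  ``converged`` reflects rhat of the core (non-latent)
    parameters only.
    """

    table: pd.DataFrame
    draws: dict[str, np.ndarray]
    converged: bool
    max_rhat: float
    method: str = ""

    def mean(self, name: str) -> float:
        return float(self.table.loc[name, "mean"])

    def sd(self, name: str) -> float:
        return float(self.table.loc[name, "sd"])


def summarize_draws(
    draws: dict[str, np.ndarray],
    core: list[str],
    rhat_threshold: float,
    method: str = "",
    diagnose_latent: bool = False,
) -> PosteriorSummary:
    """Assemble a :class:`PosteriorSummary` from named draw blocks.

    Scalar blocks have shape (chains, kept); vector blocks (chains, kept, dim)
    expand to ``name[j]`` rows.  Latent blocks (names not in ``core``) get
    diagnostics only when ``diagnose_latent`` — they do not gate convergence.
    """
    rows = []
    max_core_rhat = 0.0
    for name, arr in draws.items():
        arr3 = arr[..., None] if arr.ndim == 2 else arr
        flat = arr3.reshape(-1, arr3.shape[-1])
        want_diag = name in core or diagnose_latent
        if want_diag:
            rhat, ess = _diagnostics(arr)
        else:
            rhat = ess = np.full(arr3.shape[-1], np.nan)
        if name in core:
            max_core_rhat = max(max_core_rhat, float(np.nanmax(rhat)))
        q = np.percentile(flat, [2.5, 97.5], axis=0)
        for j in range(arr3.shape[-1]):
            label = name if arr.ndim == 2 else f"{name}[{j}]"
            rows.append(
                {
                    "parameter": label,
                    "mean": flat[:, j].mean(),
                    "sd": flat[:, j].std(ddof=1),
                    "q2.5": q[0, j],
                    "q97.5": q[1, j],
                    "rhat": rhat[j],
                    "ess": ess[j],
                }
            )
    table = pd.DataFrame(rows).set_index("parameter")
    return PosteriorSummary(
        table=table,
        draws=draws,
        converged=bool(max_core_rhat < rhat_threshold),
        max_rhat=max_core_rhat,
        method=method,
    )
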