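"""Prior specification shared by all three fitters.

Regression-type parameters (beta, gamma, alpha) get independent diffuse
Normal(0, normal_sd^2) priors; the residual SD sigma a weakly-informative
half-Cauchy(0, 5); the random-effects covariance an inverse-Wishart with
identity scale and K degrees of freedom; and, for the bias-corrected
two-stage fit only, the individual hazard multipliers w_i get an informative
Gamma(eta, eta) prior with mean 1 and variance 1/eta, eta a known constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PriorSpec", "default_priors"]


@dataclass(frozen=True)
class PriorSpec:
    normal_sd: float = 100.0  # SD of the diffuse Normal on beta, gamma, alpha
    cauchy_scale: float = 5.0  # half-Cauchy scale for sigma
    wishart_scale: np.ndarray = None  # type: ignore[assignment]  # K x K, identity
    wishart_df: int = 2  # r = K
    eta: float = 1.5  # Gamma(eta, eta) concentration for w_i

    def __post_init__(self) -> None:
        if self.wishart_scale is None:
            object.__setattr__(self, "wishart_scale", np.eye(self.wishart_df))
        if not self.normal_sd > 0 or not self.cauchy_scale > 0:
            raise ValueError("prior scales must be positive")
        if not self.eta > 0:
            raise ValueError("eta must be positive")

    @property
    def w_prior_variance(self) -> float:
        """Var(w_i) = 1/eta under the Gamma(eta, eta) prior (E(w_i) = 1)."""
        return 1.0 / self.eta


def default_priors(K: int = 2, normal_sd: float = 100.0, eta: float = 1.5) -> PriorSpec:
    """Standard diffuse priors; ``eta`` controls how hard w_i is shrunk to 1."""
    if not normal_sd > 0:
        raise ValueError("normal_sd must be positive")
    if not eta > 0:
        raise ValueError("eta must be positive")
    return PriorSpec(normal_sd=normal_sd, wishart_scale=np.eye(K), wishart_df=K, eta=eta)
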