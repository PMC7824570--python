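"""Canonical joint model: linear trajectory, exp-linear hazard, closed forms.

The longitudinal submodel is a linear mixed-effects model

    y_i(t) = (beta0 + b0i) + (beta1 + b1i) t + beta2 x_i + eps,   eps ~ N(0, sigma^2)

with subject random effects b_i ~ N(0, Sigma) (K = 2: random intercept and
slope) and a binary group covariate x_i.  The survival submodel is a
proportional-hazards model with exponential baseline h0(t) = exp(gamma0) and
the current trajectory value as a time-varying covariate:

    h_i(t) = w_i exp(gamma0 + gamma1 x_i + alpha mu_i(t)),

where w_i > 0 is an optional individual multiplier (1 outside the
bias-corrected two-stage fit).  Because mu_i(t) is linear in t the log-hazard
is linear in t, so the cumulative hazard, survival function and the inverse
of the survival function are all available in closed form; every fitter and
the simulator run on those closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LongitudinalParams",
    "SurvivalParams",
    "JointParameters",
    "SubjectRecord",
    "LinearHazard",
    "trajectory",
    "linear_hazard_coefficients",
    "cumulative_hazard",
    "survival_prob",
    "log_lik_survival",
    "log_lik_longitudinal",
    "SMALL_SLOPE",
]

#: below this |d| the cumulative hazard uses the d -> 0 limit (exp(d t) - 1 ~ d t)
SMALL_SLOPE = 1e-10


@dataclass(frozen=True)
class LongitudinalParams:
    """Fixed effects, residual SD and random-effects covariance of the mixed model."""

    beta: np.ndarray  # (beta0, beta1, beta2)
    sigma: float
    Sigma: np.ndarray  # K x K, K = 2

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        Sigma = np.asarray(self.Sigma, dtype=float)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "Sigma", Sigma)
        if beta.shape != (3,):
            raise ValueError(f"beta must have length 3, got shape {beta.shape}")
        if not np.all(np.isfinite(beta)):
            raise ValueError("beta must be finite")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if Sigma.shape != (2, 2):
            raise ValueError(f"Sigma must be 2x2, got shape {Sigma.shape}")
        if not np.allclose(Sigma, Sigma.T):
            raise ValueError("Sigma must be symmetric")
        if np.any(np.linalg.eigvalsh(Sigma) <= 0):
            raise ValueError("Sigma must be positive-definite")


@dataclass(frozen=True)
class SurvivalParams:
    """Hazard coefficients: gamma = (gamma0, gamma1), association alpha.

    ``eta`` and ``w`` only exist for the bias-corrected two-stage model, where
    w_i ~ Gamma(eta, eta) are individual multiplicative effects with prior
    mean 1 and eta is a known constant.
    """

    gamma: np.ndarray  # (gamma0 baseline log-hazard, gamma1 group coefficient)
    alpha: float
    eta: float | None = None
    w: np.ndarray | None = None

    def __post_init__(self) -> None:
        gamma = np.asarray(self.gamma, dtype=float)
        object.__setattr__(self, "gamma", gamma)
        if gamma.shape != (2,):
            raise ValueError(f"gamma must have length 2, got shape {gamma.shape}")
        if self.eta is not None and not self.eta > 0:
            raise ValueError("eta must be positive")
        if self.w is not None:
            w = np.asarray(self.w, dtype=float)
            object.__setattr__(self, "w", w)
            if np.any(w <= 0):
                raise ValueError("all w_i must be positive")


@dataclass(frozen=True)
class JointParameters:
    """Full parameter vector theta = (beta, Sigma, sigma, gamma, alpha[, eta, w])."""

    longitudinal: LongitudinalParams
    survival: SurvivalParams

    @property
    def beta(self) -> np.ndarray:
        return self.longitudinal.beta

    @property
    def sigma(self) -> float:
        return self.longitudinal.sigma

    @property
    def Sigma(self) -> np.ndarray:
        return self.longitudinal.Sigma

    @property
    def gamma(self) -> np.ndarray:
        return self.survival.gamma

    @property
    def alpha(self) -> float:
        return self.survival.alpha


@dataclass
class SubjectRecord:
    """One individual: covariate, measurements, observed time, event indicator."""

    id: int | str
    x: int
    times: np.ndarray
    y: np.ndarray
    T: float
    delta: int
    b: np.ndarray | None = None  # true random effects, simulation provenance only

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x not in (0, 1):
            raise ValueError(f"x must be 0 or 1, got {self.x}")
        if self.delta not in (0, 1):
            raise ValueError(f"delta must be 0 or 1, got {self.delta}")
        if len(self.y) != len(self.times):
            raise ValueError("y and times must have equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("measurement times must be strictly increasing")
        if not self.T > 0:
            raise ValueError("observed time T must be positive")
        if len(self.times) and self.times[-1] > self.T + 1e-12:
            raise ValueError("measurement times must not exceed the observed time")
        if self.b is not None:
            self.b = np.asarray(self.b, dtype=float)


@dataclass(frozen=True)
class LinearHazard:
    """Coefficients of a log-linear hazard h(t) = w exp(c + d t).

    For subject i under the canonical model,
    c = gamma0 + gamma1 x_i + alpha (beta0 + b0i + beta2 x_i) and
    d = alpha (beta1 + b1i); w defaults to 1.
    """

    c: float
    d: float
    w: float = 1.0

    def __post_init__(self) -> None:
        if not self.w > 0:
            raise ValueError("hazard multiplier w must be positive")


def trajectory(
    beta: Sequence[float], b: Sequence[float], x: int, t: float | np.ndarray
) -> float | np.ndarray:
    """Subject-specific mean outcome mu(t) = (b0+beta0) + (b1+beta1) t + beta2 x."""
    beta = np.asarray(beta, dtype=float)
    b = np.asarray(b, dtype=float)
    if beta.shape != (3,):
        raise ValueError(f"beta must have length 3, got shape {beta.shape}")
    if b.shape != (2,):
        raise ValueError(f"b must have length 2, got shape {b.shape}")
    return (beta[0] + b[0]) + (beta[1] + b[1]) * np.asarray(t, dtype=float) + beta[2] * x


def linear_hazard_coefficients(
    long: LongitudinalParams | Sequence[float],
    b: Sequence[float],
    surv: SurvivalParams,
    x: int,
) -> LinearHazard:
    """Collapse the hazard of one subject to its log-linear coefficients.

    Substituting the linear trajectory into the hazard gives
    h(t) = w exp(c + d t) with c and d as documented on :class:`LinearHazard`;
    the identity is exact, not an approximation.
    """
    beta = long.beta if isinstance(long, LongitudinalParams) else np.asarray(long, float)
    if beta.shape != (3,):
        raise ValueError(f"beta must have length 3, got shape {beta.shape}")
    b = np.asarray(b, dtype=float)
    if b.shape != (2,):
        raise ValueError(f"b must have length 2, got shape {b.shape}")
    g0, g1 = surv.gamma
    c = g0 + g1 * x + surv.alpha * (beta[0] + b[0] + beta[2] * x)
    d = surv.alpha * (beta[1] + b[1])
    w = 1.0 if surv.w is None else float(np.asarray(surv.w).ravel()[0])
    return LinearHazard(c=float(c), d=float(d), w=w)


def _cum_hazard_cd(
    c: np.ndarray, d: np.ndarray, w: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Vectorised H(t) = w e^c (e^{d t} - 1)/d, with the d -> 0 limit w e^c t."""
    c, d, w, t = np.broadcast_arrays(
        np.asarray(c, float), np.asarray(d, float), np.asarray(w, float), np.asarray(t, float)
    )
    small = np.abs(d) < SMALL_SLOPE
    d_safe = np.where(small, 1.0, d)
    out = np.where(
        small,
        w * np.exp(c) * t,
        w * np.exp(c) * np.expm1(d_safe * t) / d_safe,
    )
    return out


def cumulative_hazard(lh: LinearHazard, t: float | np.ndarray) -> float | np.ndarray:
    """Closed-form cumulative hazard H(t) = int_0^t w exp(c + d s) ds."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    out = _cum_hazard_cd(lh.c, lh.d, lh.w, t)
    return float(out) if out.ndim == 0 else out


def survival_prob(lh: LinearHazard, t: float | np.ndarray) -> float | np.ndarray:
    """S(t) = exp(-H(t)); S(0) = 1, nonincreasing in t."""
    return np.exp(-cumulative_hazard(lh, t))


def log_lik_survival(rec: SubjectRecord, lh: LinearHazard) -> float:
    """Right-censored log-likelihood delta log h(T) - H(T) for one subject."""
    H = cumulative_hazard(lh, rec.T)
    if rec.delta:
        return float(np.log(lh.w) + lh.c + lh.d * rec.T - H)
    return float(-H)


def log_lik_longitudinal(
    rec: SubjectRecord, beta: Sequence[float], b: Sequence[float], sigma: float
) -> float:
    """Gaussian log-likelihood of the subject's measurements about the trajectory."""
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    mu = trajectory(beta, b, rec.x, rec.times)
    resid = rec.y - mu
    n = len(rec.y)
    return float(-0.5 * n * np.log(2 * np.pi * sigma**2) - 0.5 * np.sum(resid**2) / sigma**2)
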