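"""MCMC run configuration."""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["McmcConfig"]


@dataclass(frozen=True)
class McmcConfig:
    """Chains and iteration counts; ``iterations`` is the total per chain.

    Defaults mirror the standard protocol: 2000 total with a 1000-draw
    warm-up for the joint fit and the longitudinal stage, and 1000/500 for
    the plug-in survival stage (see :func:`McmcConfig.survival_stage`).
    """

    chains: int = 2
    iterations: int = 2000
    warmup: int = 1000
    seed: int = 0
    rhat_threshold: float = 1.05
    min_ess: float = 100.0

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")

    @property
    def kept(self) -> int:
        return self.iterations - self.warmup

    @classmethod
    def survival_stage(cls, seed: int = 0, **kwargs) -> "McmcConfig":
        """Default sizing of the plug-in survival stage (1000 total, 500 warm-up)."""
        return cls(iterations=1000, warmup=500, seed=seed, **kwargs)

    def with_doubled_iterations(self) -> "McmcConfig":
        """Used for the single automatic retry after a convergence failure."""
        return replace(self, iterations=2 * self.iterations, warmup=2 * self.warmup)
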