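"""Univariate slice sampling with stepping-out (Neal 2003)."""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["slice_sweep"]


def slice_sweep(
    theta: np.ndarray,
    logpost: Callable[[np.ndarray], float],
    widths: np.ndarray,
    rng: np.random.Generator,
    cur_lp: float | None = None,
    max_steps: int = 100,
) -> tuple[np.ndarray, float]:
    """One coordinate-wise slice-sampling sweep; returns (theta, logpost(theta))."""
    theta = theta.copy()
    lp = logpost(theta) if cur_lp is None else cur_lp
    for k in range(len(theta)):
        logy = lp - rng.exponential()
        x0 = theta[k]
        L = x0 - widths[k] * rng.uniform()
        R = L + widths[k]

        def lp_at(val: float) -> float:
            theta[k] = val
            return logpost(theta)

        steps = max_steps
        while steps > 0 and lp_at(L) > logy:
            L -= widths[k]
            steps -= 1
        while steps > 0 and lp_at(R) > logy:
            R += widths[k]
            steps -= 1
        # shrinkage
        while True:
            x1 = L + (R - L) * rng.uniform()
            lp1 = lp_at(x1)
            if lp1 > logy:
                theta[k] = x1
                lp = lp1
                break
            if x1 < x0:
                L = x1
            else:
                R = x1
            if R - L < 1e-14 * (1 + abs(x0)):  # numerically exhausted interval
                theta[k] = x0
                lp = lp_at(x0)
                break
    return theta, lp
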