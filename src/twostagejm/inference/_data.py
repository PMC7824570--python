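"""Packed array view of a JointDataset plus per-subject sufficient statistics.

The mixed-model Gibbs updates only touch the data through per-subject
cross-products of the fixed design X_i = [1, t, x_i] and random design
Z_i = [1, t], so those are computed once per fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..simulate import JointDataset

__all__ = ["PackedData", "pack_dataset"]


@dataclass
class PackedData:
    # concatenated longitudinal observations
    t: np.ndarray
    y: np.ndarray
    idx: np.ndarray  # subject index per observation
    # per-subject survival data
    x: np.ndarray
    T: np.ndarray
    delta: np.ndarray
    # per-subject cross-products
    ZtZ: np.ndarray  # (n, 2, 2)
    Zty: np.ndarray  # (n, 2)
    XtZ: np.ndarray  # (n, 3, 2)
    XtX: np.ndarray  # (n, 3, 3)
    Xty: np.ndarray  # (n, 3)

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def n_obs(self) -> int:
        return len(self.y)


def pack_dataset(data: JointDataset) -> PackedData:
    subs = data.subjects
    n = len(subs)
    t = np.concatenate([s.times for s in subs])
    y = np.concatenate([s.y for s in subs])
    idx = np.concatenate([np.full(len(s.times), i) for i, s in enumerate(subs)])
    x = np.array([s.x for s in subs], dtype=float)
    T = np.array([s.T for s in subs], dtype=float)
    delta = np.array([s.delta for s in subs], dtype=float)

    m = np.bincount(idx, minlength=n).astype(float)
    St = np.bincount(idx, weights=t, minlength=n)
    St2 = np.bincount(idx, weights=t * t, minlength=n)
    Sy = np.bincount(idx, weights=y, minlength=n)
    Sty = np.bincount(idx, weights=t * y, minlength=n)

    ZtZ = np.empty((n, 2, 2))
    ZtZ[:, 0, 0] = m
    ZtZ[:, 0, 1] = ZtZ[:, 1, 0] = St
    ZtZ[:, 1, 1] = St2
    Zty = np.stack([Sy, Sty], axis=1)

    # X columns: intercept, time, group (x constant within subject, x^2 = x)
    XtZ = np.empty((n, 3, 2))
    XtZ[:, 0] = ZtZ[:, 0]
    XtZ[:, 1] = ZtZ[:, 1]
    XtZ[:, 2, 0] = m * x
    XtZ[:, 2, 1] = St * x

    XtX = np.empty((n, 3, 3))
    XtX[:, :2, :2] = ZtZ
    XtX[:, 2, :2] = XtX[:, :2, 2] = XtZ[:, 2]
    XtX[:, 2, 2] = m * x

    Xty = np.stack([Sy, Sty, Sy * x], axis=1)
    return PackedData(t=t, y=y, idx=idx, x=x, T=T, delta=delta,
                      ZtZ=ZtZ, Zty=Zty, XtZ=XtZ, XtX=XtX, Xty=Xty)


def inv2x2(A: np.ndarray) -> np.ndarray:
    """Batched inverse of (n, 2, 2) symmetric positive-definite matrices."""
    det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
    out = np.empty_like(A)
    out[:, 0, 0] = A[:, 1, 1]
    out[:, 1, 1] = A[:, 0, 0]
    out[:, 0, 1] = out[:, 1, 0] = -A[:, 0, 1]
    return out / det[:, None, None]


def sample_mvn2_from_precision(
    Q: np.ndarray, v: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw from N(Q^-1 v, Q^-1) for a batch of 2x2 precisions.

    Returns (draw, mean), each (n, 2), via the batched Cholesky of Q.
    """
    l11 = np.sqrt(Q[:, 0, 0])
    l21 = Q[:, 1, 0] / l11
    l22 = np.sqrt(Q[:, 1, 1] - l21**2)
    # mean: solve L L^T m = v
    w1 = v[:, 0] / l11
    w2 = (v[:, 1] - l21 * w1) / l22
    m2 = w2 / l22
    m1 = (w1 - l21 * m2) / l11
    mean = np.stack([m1, m2], axis=1)
    z = rng.standard_normal(v.shape)
    u2 = z[:, 1] / l22
    u1 = (z[:, 0] - l21 * u2) / l11
    return mean + np.stack([u1, u2], axis=1), mean
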