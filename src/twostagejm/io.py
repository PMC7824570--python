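"""Dataset, summary and manifest readers/writers.

Interchange formats are deliberately plain: comma-separated UTF-8 text with
mandatory headers and period decimals, numbers written with 17 significant
digits so a round trip is lossless.  The longitudinal file has columns
``id,time,y,x`` (long format, one row per measurement) and the survival file
``id,T,delta,x`` (one row per subject).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model_core import SubjectRecord
from .simulate import JointDataset
from .inference import PosteriorSummary

__all__ = [
    "read_joint_dataset",
    "write_joint_dataset",
    "write_posterior_summary",
    "write_truth_manifest",
    "RunManifest",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"


def write_joint_dataset(
    data: JointDataset, long_path: str | Path, surv_path: str | Path
) -> None:
    """Write the two CSV files; row order is by id then time, so output is
    deterministic and identical datasets serialise byte-identically."""
    subs = sorted(data.subjects, key=lambda s: (str(type(s.id)), s.id))
    long_rows = {
        "id": np.concatenate([[s.id] * len(s.times) for s in subs]) if subs else [],
        "time": np.concatenate([s.times for s in subs]) if subs else [],
        "y": np.concatenate([s.y for s in subs]) if subs else [],
        "x": np.concatenate([[s.x] * len(s.times) for s in subs]) if subs else [],
    }
    pd.DataFrame(long_rows).to_csv(long_path, index=False, float_format=_FLOAT_FMT)
    surv_rows = {
        "id": [s.id for s in subs],
        "T": [s.T for s in subs],
        "delta": [s.delta for s in subs],
        "x": [s.x for s in subs],
    }
    pd.DataFrame(surv_rows).to_csv(surv_path, index=False, float_format=_FLOAT_FMT)


def read_joint_dataset(long_path: str | Path, surv_path: str | Path) -> JointDataset:
    """Assemble subjects from the two CSVs, validating every record invariant."""
    long_df = pd.read_csv(long_path, float_precision="round_trip")
    surv_df = pd.read_csv(surv_path, float_precision="round_trip")
    for df, path, cols in (
        (long_df, long_path, {"id", "time", "y", "x"}),
        (surv_df, surv_path, {"id", "T", "delta", "x"}),
    ):
        missing = cols - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if surv_df["id"].duplicated().any():
        dup = surv_df.loc[surv_df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate id {dup!r} in survival file")

    surv = surv_df.set_index("id")
    subjects = []
    grouped = dict(tuple(long_df.groupby("id", sort=False)))
    for sid in surv.index:
        if sid not in grouped:
            raise ValueError(f"id {sid!r} present in survival file but has no measurements")
        g = grouped.pop(sid)
        row = surv.loc[sid]
        if not np.all(g["x"].values == row["x"]):
            bad = g.index[g["x"].values != row["x"]][0] + 2  # header + 0-base
            raise ValueError(f"id {sid!r}: covariate x inconsistent at row {bad} of longitudinal file")
        times = g["time"].to_numpy(dtype=float)
        order = np.argsort(times, kind="stable")
        times = times[order]
        if np.any(times > row["T"] + 1e-12):
            j = int(np.flatnonzero(times > row["T"] + 1e-12)[0])
            raise ValueError(
                f"id {sid!r}: measurement time {times[j]} exceeds observed time {row['T']} "
                f"(longitudinal row {int(g.index[order[j]]) + 2})"
            )
        if int(row["delta"]) not in (0, 1):
            raise ValueError(f"id {sid!r}: delta must be 0 or 1, got {row['delta']}")
        subjects.append(
            SubjectRecord(
                id=sid,
                x=int(row["x"]),
                times=times,
                y=g["y"].to_numpy(dtype=float)[order],
                T=float(row["T"]),
                delta=int(row["delta"]),
            )
        )
    if grouped:
        sid = next(iter(grouped))
        raise ValueError(f"id {sid!r} present in longitudinal file but not in survival file")
    return JointDataset(subjects=subjects)


def write_posterior_summary(summary: PosteriorSummary, path: str | Path) -> None:
    """Posterior summary table (parameter, mean, sd, q2.5, q97.5, rhat, ess) as CSV."""
    summary.table.to_csv(path, float_format=_FLOAT_FMT)


def write_truth_manifest(data: JointDataset, path: str | Path) -> None:
    """JSON record of the simulation truth, seed and per-subject random effects."""
    if data.config is None:
        raise ValueError("dataset has no simulation provenance")
    cfg = data.config
    doc = {
        "beta": cfg.truth.beta.tolist(),
        "sigma": cfg.truth.sigma,
        "Sigma": cfg.truth.Sigma.tolist(),
        "gamma": cfg.truth.gamma.tolist(),
        "alpha": cfg.truth.alpha,
        "n": cfg.n,
        "m_min": cfg.m_min,
        "t_max": cfg.t_max,
        "seed": cfg.seed,
        "event_rate": data.event_rate,
        "b": [s.b.tolist() if s.b is not None else None for s in data.subjects],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance of one CLI run: enough to regenerate its outputs exactly."""

    command: str
    config: dict
    master_seed: int | None
    inputs: dict[str, str]  # path -> sha256
    outputs: dict[str, str]
    version: str = __version__
    started: str = ""
    finished: str = ""


def write_manifest(
    path: str | Path,
    command: str,
    config: dict,
    master_seed: int | None,
    inputs: list[str | Path],
    outputs: list[str | Path],
    started: float,
) -> RunManifest:
    man = RunManifest(
        command=command,
        config=config,
        master_seed=master_seed,
        inputs={str(p): _digest(p) for p in inputs},
        outputs={str(p): _digest(p) for p in outputs},
        started=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime(started)),
        finished=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    )
    Path(path).write_text(json.dumps(dataclasses.asdict(man), indent=1))
    return man
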