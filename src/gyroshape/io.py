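"""Readers and writers for the trajectory and clinical CSV dialects.

Trajectory CSV: columns ``subject_id, visit, activity, t, gyro_y``; one
repetition per (subject_id, visit, activity) group; header required; rows of
a repetition must appear in time order.  On read, repetitions are validated
and resampled to a common uniform grid on [0, 1].
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import MIN_SAMPLES, Trajectory, resample

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "read_clinical",
    "TrajectoryFormatError",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "visit", "activity", "t", "gyro_y")
COHORTS = ("DMD", "SMA", "Healthy")


class TrajectoryFormatError(ValueError):
    """Malformed trajectory CSV content."""


def read_trajectories(
    path: str | Path, grid_length: int = 200, strict: bool = True
) -> list[Trajectory]:
    """Read repetitions from CSV and resample each to ``grid_length`` samples.

    A repetition whose time column is not strictly increasing in file order,
    or that has fewer than 8 samples, is rejected: raised in ``strict`` mode,
    otherwise skipped with a logged warning naming the repetition key.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing required columns {missing}")
    bad = df[~np.isfinite(df["t"]) | ~np.isfinite(df["gyro_y"])]
    if len(bad):
        lines = (bad.index + 2).tolist()[:10]  # +2: header + 0-base
        raise TrajectoryFormatError(f"{path}: non-finite t/gyro_y at lines {lines}")

    out: list[Trajectory] = []
    for (sid, visit, activity), grp in df.groupby(
        ["subject_id", "visit", "activity"], sort=True
    ):
        key = f"(subject_id={sid}, visit={visit}, activity={activity})"
        t = grp["t"].to_numpy(dtype=float)
        y = grp["gyro_y"].to_numpy(dtype=float)
        problem = None
        if t.size < MIN_SAMPLES:
            problem = f"only {t.size} samples (need >= {MIN_SAMPLES})"
        elif np.any(np.diff(t) <= 0):
            problem = "time not strictly increasing within the repetition"
        if problem:
            if strict:
                raise TrajectoryFormatError(f"{path}: repetition {key}: {problem}")
            logger.warning("skipping repetition %s: %s", key, problem)
            continue
        grid, vals = resample(t, y, grid_length)
        out.append(
            Trajectory(grid, vals, subject_id=str(sid), visit=int(visit),
                       activity=str(activity))
        )
    return out


def write_trajectories(path: str | Path, trajectories: list[Trajectory]) -> None:
    """Write repetitions to the trajectory CSV dialect."""
    frames = []
    for tr in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": tr.subject_id,
                    "visit": tr.visit,
                    "activity": tr.activity,
                    "t": tr.grid,
                    "gyro_y": tr.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read and validate the clinical covariate table.

    Requires subject_id, cohort in {DMD, SMA, Healthy}, age > 0; the Brooke
    score, when present, must lie in 1..6.
    """
    df = pd.read_csv(path)
    required = ["subject_id", "cohort", "age"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing clinical columns {missing}")
    bad_cohort = ~df["cohort"].isin(COHORTS)
    if bad_cohort.any():
        raise TrajectoryFormatError(
            f"{path}: invalid cohort labels {sorted(df.loc[bad_cohort, 'cohort'].unique())}"
        )
    if (df["age"] <= 0).any():
        raise TrajectoryFormatError(f"{path}: age must be > 0")
    if "brooke" in df.columns:
        b = df["brooke"].dropna()
        if ((b < 1) | (b > 6)).any():
            raise TrajectoryFormatError(f"{path}: brooke must be within 1..6")
    return df
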