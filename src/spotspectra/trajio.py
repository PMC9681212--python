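"""Trajectory table input/output.

The on-disk format is delimited text (CSV) with columns
``trajectory_id, frame, x_um, y_um``; extra columns round-trip untouched.
Positions are written at 6 decimal places (sub-nanometer), which the
reader treats as lossless.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_trajectories", "write_trajectories", "validate_trajectories"]

REQUIRED_COLUMNS = ["trajectory_id", "frame", "x_um", "y_um"]


def validate_trajectories(dataset: pd.DataFrame) -> pd.DataFrame:
    """Check schema and the no-gap invariant; returns the sorted table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in dataset.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    out = dataset.sort_values(["trajectory_id", "frame"]).reset_index(drop=True)
    if len(out) == 0:
        return out
    tid = out["trajectory_id"].to_numpy()
    frame = out["frame"].to_numpy()
    same = tid[1:] == tid[:-1]
    gaps = same & (np.diff(frame) != 1)
    if np.any(gaps):
        bad = np.unique(tid[1:][gaps])
        raise ValueError(f"non-consecutive frames within trajectory id(s): {bad[:10].tolist()}")
    return out


def write_trajectories(dataset: pd.DataFrame, path: str) -> None:
    """Write a trajectory table as CSV (positions at 6 decimals)."""
    validate_trajectories(dataset).to_csv(path, index=False, float_format="%.6f")


def read_trajectories(path: str) -> pd.DataFrame:
    """Read and validate a trajectory table; empty files with a header are fine."""
    data = pd.read_csv(path)
    return validate_trajectories(data)
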