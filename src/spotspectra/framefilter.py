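"""Dense-frame filter.

Occasional frames with many detections risk misconnections, so they are
removed: per-frame detection counts are smoothed with a centered uniform
kernel (width 21 frames by default, truncated to the available frames at
the sequence edges) and only frames whose smoothed count is strictly below
the cutoff (7 by default) are kept.  Trajectories are then rebuilt from
kept frames only, splitting wherever a frame was removed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import FrameFilterConfig

__all__ = ["smooth_counts", "filter_dense_frames", "apply_frame_filter", "detection_counts"]


def detection_counts(dataset: pd.DataFrame, n_frames: int | None = None) -> np.ndarray:
    """Per-frame detection counts from a trajectory/detection table."""
    if n_frames is None:
        n_frames = int(dataset["frame"].max()) + 1 if len(dataset) else 0
    counts = np.zeros(n_frames, dtype=float)
    if len(dataset):
        vals, n = np.unique(dataset["frame"].to_numpy(), return_counts=True)
        counts[vals.astype(int)] = n
    return counts


def smooth_counts(counts: np.ndarray, kernel_frames: int = 21) -> np.ndarray:
    """Centered uniform smoothing with truncated-window means at the edges."""
    counts = np.asarray(counts, dtype=float)
    half = kernel_frames // 2
    csum = np.concatenate([[0.0], np.cumsum(counts)])
    n = counts.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def filter_dense_frames(
    counts: np.ndarray, config: FrameFilterConfig | None = None
) -> np.ndarray:
    """Kept frames: those whose smoothed detection count is < the cutoff.

    Frames whose smoothed count equals the cutoff exactly are removed
    (``keep_strictly_below=True``, the default).
    """
    config = config or FrameFilterConfig()
    smoothed = smooth_counts(counts, config.smooth_kernel_frames)
    if config.keep_strictly_below:
        kept = smoothed < config.max_smoothed_count
    else:
        kept = smoothed <= config.max_smoothed_count
    return np.flatnonzero(kept)


def apply_frame_filter(
    dataset: pd.DataFrame,
    kept_frames: np.ndarray,
) -> pd.DataFrame:
    """Rebuild trajectories from kept frames only, splitting at removed frames.

    Retains only rows whose frame is kept, then re-keys trajectory ids so
    every output trajectory covers strictly consecutive frames.
    """
    if len(dataset) == 0:
        return dataset.copy()
    kept_set = set(int(f) for f in np.asarray(kept_frames).ravel())
    sub = dataset[dataset["frame"].isin(kept_set)].copy()
    if len(sub) == 0:
        return sub.reset_index(drop=True)
    sub = sub.sort_values(["trajectory_id", "frame"])
    breaks = (sub["trajectory_id"].diff() != 0) | (sub["frame"].diff() != 1)
    sub["trajectory_id"] = breaks.cumsum().astype(int) - 1
    return sub.reset_index(drop=True)
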