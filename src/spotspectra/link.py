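"""Frame-to-frame linking of detections into trajectories.

Between consecutive frames, detections are matched by a globally optimal
one-to-one assignment minimizing summed squared Euclidean distances, with
links longer than the search radius forbidden.  There is no gap closing
(max_blinks = 0): unmatched detections start new trajectories, and frames
holding more than ``max_spots_per_frame`` detections are excluded from
linking entirely, breaking all trajectories there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .config import LinkConfig
from .detect import SpotDetection

__all__ = ["Trajectory", "link_detections", "trajectories_to_frame", "brute_force_assignment"]

_FORBIDDEN = 1e12


@dataclass
class Trajectory:
    """Time-ordered positions of one molecule across consecutive frames."""

    id: int
    frames: list[int] = field(default_factory=list)
    x_um: list[float] = field(default_factory=list)
    y_um: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def append(self, frame: int, x: float, y: float) -> None:
        if self.frames and frame != self.frames[-1] + 1:
            raise ValueError("trajectory frames must be strictly consecutive")
        self.frames.append(frame)
        self.x_um.append(x)
        self.y_um.append(y)


def _assignment(cost: np.ndarray, radius: float) -> list[tuple[int, int]]:
    """Optimal one-to-one matching; pairs with cost > radius² are dropped."""
    masked = np.where(cost <= radius**2, cost, _FORBIDDEN)
    rows, cols = linear_sum_assignment(masked)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if masked[i, j] < _FORBIDDEN]


def brute_force_assignment(cost: np.ndarray, radius: float) -> list[tuple[int, int]]:
    """Exhaustive-enumeration oracle for the same matching objective.

    Enumerates every complete one-to-one matching (padding the smaller
    side), scoring forbidden links with a large constant, and returns the
    allowed links of the minimum-cost matching.  Only feasible for tiny
    instances; used to pin the behavior of :func:`_assignment` in tests.
    """
    n, m = cost.shape
    masked = np.where(cost <= radius**2, cost, _FORBIDDEN)
    if n <= m:
        best, best_cost = None, np.inf
        for perm in permutations(range(m), n):
            c = sum(masked[i, j] for i, j in enumerate(perm))
            if c < best_cost - 1e-12:
                best_cost, best = c, perm
        pairs = list(enumerate(best))
    else:
        best, best_cost = None, np.inf
        for perm in permutations(range(n), m):
            c = sum(masked[i, j] for j, i in enumerate(perm))
            if c < best_cost - 1e-12:
                best_cost, best = c, perm
        pairs = [(i, j) for j, i in enumerate(best)]
    return [(i, j) for i, j in pairs if masked[i, j] < _FORBIDDEN]


def link_detections(
    detections: list[SpotDetection],
    config: LinkConfig | None = None,
    pixel_size_um: float = 1.0,
) -> list[Trajectory]:
    """Link localized detections into trajectories.

    Detections must carry pixel positions; µm coordinates are derived via
    ``pixel_size_um`` when not already present.  Detections in frames with
    more than ``max_spots_per_frame`` spots become unlinked singleton
    trajectories.
    """
    config = config or LinkConfig()
    if not detections:
        return []

    by_frame: dict[int, list[SpotDetection]] = {}
    for det in detections:
        if det.x_um is None or det.y_um is None:
            det.x_um = det.x_px * pixel_size_um
            det.y_um = det.y_px * pixel_size_um
        by_frame.setdefault(int(det.frame), []).append(det)

    frames = sorted(by_frame)
    linkable = {f: len(by_frame[f]) <= config.max_spots_per_frame for f in frames}

    trajectories: list[Trajectory] = []
    # active[i] = index into trajectories for each detection of the previous frame
    prev_frame: int | None = None
    active: list[int] = []

    for f in frames:
        dets = by_frame[f]
        pos = np.array([[d.x_um, d.y_um] for d in dets])
        assigned = [None] * len(dets)

        can_link = (
            prev_frame is not None
            and f == prev_frame + 1
            and linkable[f]
            and prev_frame in linkable
            and linkable[prev_frame]
            and len(active) > 0
        )
        if can_link:
            prev_pos = np.array(
                [[trajectories[t].x_um[-1], trajectories[t].y_um[-1]] for t in active]
            )
            cost = ((prev_pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
            for i, j in _assignment(cost, config.search_radius_um):
                assigned[j] = active[i]

        new_active = []
        for j, det in enumerate(dets):
            if assigned[j] is None:
                trajectories.append(Trajectory(id=len(trajectories)))
                tid = len(trajectories) - 1
            else:
                tid = assigned[j]
            trajectories[tid].append(f, det.x_um, det.y_um)
            new_active.append(tid)

        # Dense frames break everything: nothing continues out of them.
        active = new_active if linkable[f] else []
        prev_frame = f

    return trajectories


def trajectories_to_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Convert trajectories to the standard table (trajectory_id, frame, x_um, y_um)."""
    if not trajectories:
        return pd.DataFrame(columns=["trajectory_id", "frame", "x_um", "y_um"])
    rows = {
        "trajectory_id": np.concatenate(
            [np.full(len(t), t.id, dtype=int) for t in trajectories]
        ),
        "frame": np.concatenate([np.asarray(t.frames, dtype=int) for t in trajectories]),
        "x_um": np.concatenate([np.asarray(t.x_um) for t in trajectories]),
        "y_um": np.concatenate([np.asarray(t.y_um) for t in trajectories]),
    }
    return pd.DataFrame(rows).sort_values(["trajectory_id", "frame"]).reset_index(drop=True)
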