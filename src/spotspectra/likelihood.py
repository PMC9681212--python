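"""Trajectory likelihoods under regular Brownian motion with localization error.

The observation model (RBME): true positions follow Brownian motion with
diffusion coefficient D; each observed position adds i.i.d. Gaussian error
of standard deviation σ per axis.  The vector of n successive jumps along
one axis is then zero-mean multivariate normal with tridiagonal covariance

    C = (2 D Δt + 2 σ²) on the diagonal,  -σ² on the first off-diagonals.

C = 2DΔt·I + σ²·T with T the second-difference matrix tridiag(-1, 2, -1),
whose eigenvectors are discrete sines — so likelihoods over a whole (D, σ)
grid reduce, per trajectory, to one orthogonal transform of its jumps plus
per-state diagonal Gaussian terms.  x and y axes are independent and
identically distributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .config import AcquisitionConfig
from .grids import StateGrid

__all__ = [
    "rbme_jump_covariance",
    "trajectory_log_likelihood",
    "LikelihoodMatrix",
    "build_likelihood_matrix",
    "naive_cell_occupations",
]

# Variance floor guarding the (D=0, σ=0) degenerate corner.
_VAR_FLOOR = 1e-14


def rbme_jump_covariance(D: float, sigma: float, dt: float, n_jumps: int) -> np.ndarray:
    """Per-axis covariance of ``n_jumps`` successive observed jumps.

    Parameters are the diffusion coefficient (µm²/s), localization error
    (µm), frame interval (s) and the number of jumps.  Returns the
    (n_jumps, n_jumps) tridiagonal covariance in µm².
    """
    if dt <= 0:
        raise ValueError("frame interval must be positive")
    if D < 0 or sigma < 0:
        raise ValueError("D and sigma must be non-negative")
    if n_jumps < 1:
        raise ValueError("n_jumps must be >= 1")
    diag = np.full(n_jumps, 2.0 * D * dt + 2.0 * sigma**2)
    cov = np.diag(diag)
    off = -(sigma**2)
    idx = np.arange(n_jumps - 1)
    cov[idx, idx + 1] = off
    cov[idx + 1, idx] = off
    return cov


@lru_cache(maxsize=4096)
def _sine_basis(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal eigenvectors U and eigenvalues λ of tridiag(-1, 2, -1).

    U[j, k] = sqrt(2/(n+1)) sin((j+1)(k+1)π/(n+1)); λ_k = 2 - 2cos((k+1)π/(n+1)).
    """
    j = np.arange(1, n + 1)
    U = np.sqrt(2.0 / (n + 1)) * np.sin(np.outer(j, j) * np.pi / (n + 1))
    lam = 2.0 - 2.0 * np.cos(j * np.pi / (n + 1))
    return U, lam


def _jumps(traj: pd.DataFrame) -> np.ndarray:
    """(n_jumps, 2) array of (dx, dy) jumps from one trajectory's rows."""
    t = traj.sort_values("frame")
    if np.any(np.diff(t["frame"].to_numpy()) != 1):
        raise ValueError("trajectory frames must be strictly consecutive")
    return np.column_stack(
        [np.diff(t["x_um"].to_numpy()), np.diff(t["y_um"].to_numpy())]
    )


def trajectory_log_likelihood(
    traj: pd.DataFrame | np.ndarray, D: float, sigma: float, dt: float
) -> float:
    """Log-likelihood of one trajectory under RBME with state (D, σ).

    ``traj`` may be a trajectory table (frame, x_um, y_um) or a pre-computed
    (n_jumps, 2) jump array.  Sums the zero-mean multivariate normal
    log-density over the x and y axes.
    """
    jumps = traj if isinstance(traj, np.ndarray) else _jumps(traj)
    n = jumps.shape[0]
    if n < 1:
        raise ValueError("trajectory must contain at least one jump")
    U, lam = _sine_basis(n)
    v = np.maximum(2.0 * D * dt + sigma**2 * lam, _VAR_FLOOR)
    w = U.T @ jumps  # (n, 2) transformed jumps
    quad = (w**2 / v[:, None]).sum()
    logdet_terms = np.log(2.0 * np.pi * v).sum()
    return float(-logdet_terms - 0.5 * quad)


@dataclass
class LikelihoodMatrix:
    """Row-normalized trajectory likelihoods over a (D, σ) state grid.

    ``values`` has one row per trajectory with >= 1 jump and one column per
    flattened grid state (D-major: column index = i_D * n_sigma + i_sigma).
    ``jump_counts`` holds each row's number of jumps; rows sum to one.
    """

    grid: StateGrid
    values: np.ndarray
    jump_counts: np.ndarray
    trajectory_ids: np.ndarray
    n_dropped: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def n_trajectories(self) -> int:
        return self.values.shape[0]

    @property
    def total_jumps(self) -> int:
        return int(self.jump_counts.sum())

    def values_2d(self) -> np.ndarray:
        """Likelihoods reshaped to (n_trajectories, n_D, n_sigma)."""
        nD, nS = self.grid.shape
        return self.values.reshape(self.n_trajectories, nD, nS)


def _group_jump_arrays(dataset: pd.DataFrame) -> tuple[list[int], list[np.ndarray]]:
    ids: list[int] = []
    jump_arrays: list[np.ndarray] = []
    for tid, grp in dataset.groupby("trajectory_id", sort=True):
        g = grp.sort_values("frame")
        if len(g) < 2:
            continue
        if np.any(np.diff(g["frame"].to_numpy()) != 1):
            raise ValueError(f"trajectory {tid} has non-consecutive frames")
        ids.append(tid)
        jump_arrays.append(
            np.column_stack(
                [np.diff(g["x_um"].to_numpy()), np.diff(g["y_um"].to_numpy())]
            )
        )
    return ids, jump_arrays


def build_likelihood_matrix(
    dataset: pd.DataFrame, grid: StateGrid, acq: AcquisitionConfig
) -> LikelihoodMatrix:
    """Evaluate every trajectory's RBME likelihood across the state grid.

    Trajectories with fewer than one jump (single detections) are dropped
    and counted in ``n_dropped``.  Rows are normalized to sum to one; the
    computation batches trajectories by jump count so each batch costs one
    orthogonal transform plus diagonal Gaussian terms per grid state.
    """
    if len(dataset) == 0:
        raise ValueError("empty trajectory dataset")
    ids, jump_arrays = _group_jump_arrays(dataset)
    n_total = dataset["trajectory_id"].nunique()
    n_dropped = n_total - len(ids)
    if not ids:
        raise ValueError("no trajectory has >= 1 jump")

    dt = acq.frame_interval_s
    D = grid.diff_coefs
    S = grid.loc_errors
    nD, nS = grid.shape
    n_rows = len(ids)
    counts = np.array([j.shape[0] for j in jump_arrays])
    order = np.argsort(counts, kind="stable")

    log_l = np.empty((n_rows, nD * nS))
    # Batch rows sharing a jump count n: transform jumps once, then sweep states.
    pos = 0
    while pos < n_rows:
        n = counts[order[pos]]
        end = pos
        while end < n_rows and counts[order[end]] == n:
            end += 1
        batch = order[pos:end]
        U, lam = _sine_basis(int(n))
        # stacked squared transformed jumps, summed over x and y: (batch, n)
        sq = np.stack(
            [((U.T @ jump_arrays[i]) ** 2).sum(axis=1) for i in batch], axis=0
        )
        # variances per state: (nD, nS, n)
        v = 2.0 * D[:, None, None] * dt + (S[None, :, None] ** 2) * lam[None, None, :]
        v = np.maximum(v, _VAR_FLOOR)
        logdet = np.log(2.0 * np.pi * v).sum(axis=2)  # (nD, nS)
        inv_v = (1.0 / v).reshape(nD * nS, int(n))
        quad = sq @ inv_v.T  # (batch, nD*nS)
        log_l[batch] = -logdet.reshape(1, -1) - 0.5 * quad
        pos = end

    log_l -= logsumexp(log_l, axis=1, keepdims=True)
    return LikelihoodMatrix(
        grid=grid,
        values=np.exp(log_l),
        jump_counts=counts,
        trajectory_ids=np.array(ids),
        n_dropped=n_dropped,
        metadata={"frame_interval_s": dt, "n_trajectories_input": n_total},
    )


def naive_cell_occupations(
    cell_dataset: pd.DataFrame, grid: StateGrid, acq: AcquisitionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell naive occupation estimate over (D, σ), and its D-marginal.

    The jump-count-weighted average of row-normalized RBME likelihoods —
    the quick per-cell estimate used to inspect cell-to-cell variation
    without refining a posterior.  Returns ``(map_2d, d_marginal)`` where
    ``map_2d`` has shape (n_D, n_sigma) and sums to one.
    """
    L = build_likelihood_matrix(cell_dataset, grid, acq)
    weights = L.jump_counts.astype(float)
    mean_map = (weights[:, None] * L.values).sum(axis=0) / weights.sum()
    mean_map = mean_map / mean_map.sum()
    map_2d = mean_map.reshape(grid.shape)
    return map_2d, map_2d.sum(axis=1)
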