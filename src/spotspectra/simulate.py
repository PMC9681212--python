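"""Synthetic fast-SPT data with the statistical structure the analysis assumes.

Molecules are assigned a diffusive state, perform 3-D Brownian motion, and
are observed only while (i) unbleached and (ii) within a thin axial
detection slab of depth ``dz`` centered on the focal plane.  Observed x/y
positions carry i.i.d. Gaussian localization error.  Because the tracker
downstream does no gap closing, a molecule that leaves the slab and
re-enters is emitted as a *new* observed trajectory.

Axial geometry: free diffusion on a reflecting domain spanning ±5·dz about
focus, with molecules initialized uniformly inside the slab (everything
present is detected in the first frame, matching sparse-labeling
acquisitions that track from frame 0).  Lateral positions are unbounded for
trajectory output; movie rendering wraps them periodically into the field
of view so spot density stays stationary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .grids import DiffusionSpectrum, StateGrid
from .config import AcquisitionConfig

__all__ = [
    "DiffusiveState",
    "SimulationModel",
    "sample_trajectories",
    "render_movie",
    "ground_truth_spectrum",
    "reflect_into",
]

# Axial domain half-width, in units of dz.
AXIAL_DOMAIN_FACTOR = 5.0


@dataclass
class DiffusiveState:
    """One diffusive subpopulation: a diffusion coefficient and its occupation."""

    diff_coef: float
    occupation: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.diff_coef <= 100.0):
            raise ValueError("diff_coef must lie in [0, 100] µm²/s")
        if not (0.0 <= self.occupation <= 1.0):
            raise ValueError("occupation must lie in [0, 1]")


@dataclass
class SimulationModel:
    """Ground-truth mixture of diffusive states plus observation parameters.

    Parameters
    ----------
    states
        Diffusive states; occupations must sum to 1.
    loc_error_um
        Standard deviation σ of the Gaussian localization error per axis, µm.
    bleach_prob_per_frame
        Probability that a fluorophore photobleaches at each frame
        transition (single-step bleaching).
    initial_density_per_frame
        Expected number of detections in the first frame (~10 for sparse
        labeling); equals the expected number of molecules per cell since
        all molecules start inside the slab.
    state_switching, switch_prob_per_frame
        Optional within-trajectory state switching for robustness tests
        (off by default; the inference assumes one state per trajectory).
    """

    states: list[DiffusiveState] = field(
        default_factory=lambda: [DiffusiveState(0.005, 0.4), DiffusiveState(3.0, 0.6)]
    )
    loc_error_um: float = 0.035
    bleach_prob_per_frame: float = 0.02
    initial_density_per_frame: float = 10.0
    state_switching: bool = False
    switch_prob_per_frame: float = 0.0

    def __post_init__(self) -> None:
        if len(self.states) == 0:
            raise ValueError("at least one diffusive state is required")
        total = sum(s.occupation for s in self.states)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"state occupations must sum to 1 (got {total})")
        if not (0.0 <= self.loc_error_um <= 0.2):
            raise ValueError("loc_error_um must lie in [0, 0.2] µm")
        if not (0.0 <= self.bleach_prob_per_frame < 1.0):
            raise ValueError("bleach_prob_per_frame must lie in [0, 1)")
        if self.initial_density_per_frame <= 0:
            raise ValueError("initial_density_per_frame must be positive")

    @property
    def occupations(self) -> np.ndarray:
        return np.array([s.occupation for s in self.states])

    @property
    def diff_coefs(self) -> np.ndarray:
        return np.array([s.diff_coef for s in self.states])


def reflect_into(z: np.ndarray, half_width: float) -> np.ndarray:
    """Fold unbounded coordinates into [-half_width, half_width] by reflection."""
    period = 4.0 * half_width
    w = np.mod(z + half_width, period)
    return half_width - np.abs(2.0 * half_width - w)


def _bleach_lifetimes(rng: np.random.Generator, n: int, p: float, n_frames: int) -> np.ndarray:
    """Number of frames each molecule stays fluorescent (alive frames 0..L-1)."""
    if p == 0.0:
        return np.full(n, n_frames, dtype=int)
    return np.minimum(rng.geometric(p, size=n), n_frames)


def sample_trajectories(
    model: SimulationModel,
    acq: AcquisitionConfig,
    seed: int,
    n_molecules: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cell's movie worth of molecules and emit observed trajectories.

    Parameters
    ----------
    model, acq
        Ground-truth mixture and acquisition geometry.
    seed
        Seed for all randomness; identical inputs give identical outputs.
    n_molecules
        Override the Poisson draw of the molecule count (used by tests).

    Returns
    -------
    trajectories : DataFrame
        Columns ``trajectory_id, frame, x_um, y_um`` plus truth columns
        ``molecule_id`` and ``state_index``.  Each trajectory covers
        strictly consecutive frames.
    truth : DataFrame
        Per molecule and frame: true 3-D position, state index and the
        detected flag (unbleached and inside the slab).
    """
    rng = np.random.default_rng(seed)
    dt = acq.frame_interval_s
    dz = acq.focal_depth_um
    half_slab = dz / 2.0
    z_half_width = AXIAL_DOMAIN_FACTOR * dz
    n_frames = acq.n_frames
    fov_h_um, fov_w_um = acq.fov_um

    if n_molecules is None:
        n_molecules = int(rng.poisson(model.initial_density_per_frame))
    n_states = len(model.states)
    state_idx = rng.choice(n_states, size=n_molecules, p=model.occupations)
    diff_coefs = model.diff_coefs

    lifetimes = _bleach_lifetimes(rng, n_molecules, model.bleach_prob_per_frame, n_frames)

    # Per-frame state labels (constant unless switching is enabled).
    states_t = np.broadcast_to(state_idx[:, None], (n_molecules, n_frames)).copy()
    if model.state_switching and model.switch_prob_per_frame > 0 and n_molecules > 0:
        for t in range(1, n_frames):
            flip = rng.random(n_molecules) < model.switch_prob_per_frame
            states_t[:, t] = np.where(
                flip,
                rng.choice(n_states, size=n_molecules, p=model.occupations),
                states_t[:, t - 1],
            )

    # Brownian increments: per-axis variance 2 D dt, with D taken per frame
    # transition from the state occupied at the start of the step.
    d_step = diff_coefs[states_t[:, :-1]] if n_frames > 1 else np.zeros((n_molecules, 0))
    step_sd = np.sqrt(2.0 * d_step * dt)
    shape = (n_molecules, max(n_frames - 1, 0))
    dx = rng.standard_normal(shape) * step_sd
    dy = rng.standard_normal(shape) * step_sd
    dzi = rng.standard_normal(shape) * step_sd

    x0 = rng.uniform(0.0, fov_w_um, size=n_molecules)
    y0 = rng.uniform(0.0, fov_h_um, size=n_molecules)
    z0 = rng.uniform(-half_slab, half_slab, size=n_molecules)

    x = np.concatenate([x0[:, None], x0[:, None] + np.cumsum(dx, axis=1)], axis=1)
    y = np.concatenate([y0[:, None], y0[:, None] + np.cumsum(dy, axis=1)], axis=1)
    z_free = np.concatenate([z0[:, None], z0[:, None] + np.cumsum(dzi, axis=1)], axis=1)
    z = reflect_into(z_free, z_half_width)

    frames = np.arange(n_frames)
    alive = frames[None, :] < lifetimes[:, None]
    in_slab = np.abs(z) <= half_slab
    detected = alive & in_slab

    loc_err_x = rng.standard_normal((n_molecules, n_frames)) * model.loc_error_um
    loc_err_y = rng.standard_normal((n_molecules, n_frames)) * model.loc_error_um

    truth = pd.DataFrame(
        {
            "molecule_id": np.repeat(np.arange(n_molecules), n_frames),
            "frame": np.tile(frames, n_molecules),
            "x_um": x.ravel(),
            "y_um": y.ravel(),
            "z_um": z.ravel(),
            "state_index": states_t.ravel(),
            "detected": detected.ravel(),
        }
    )

    # Split each molecule's detected frames into runs of consecutive frames;
    # each run becomes its own observed trajectory (no gap closing).
    recs: list[pd.DataFrame] = []
    traj_id = 0
    obs_x = x + loc_err_x
    obs_y = y + loc_err_y
    for m in range(n_molecules):
        det_frames = frames[detected[m]]
        if det_frames.size == 0:
            continue
        breaks = np.where(np.diff(det_frames) > 1)[0] + 1
        for run in np.split(det_frames, breaks):
            recs.append(
                pd.DataFrame(
                    {
                        "trajectory_id": traj_id,
                        "frame": run,
                        "x_um": obs_x[m, run],
                        "y_um": obs_y[m, run],
                        "molecule_id": m,
                        "state_index": state_idx[m],
                    }
                )
            )
            traj_id += 1
    if recs:
        trajectories = pd.concat(recs, ignore_index=True)
    else:
        trajectories = pd.DataFrame(
            columns=["trajectory_id", "frame", "x_um", "y_um", "molecule_id", "state_index"]
        )
    return trajectories, truth


def sample_cells(
    model: SimulationModel,
    acq: AcquisitionConfig,
    n_cells: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate ``n_cells`` independent cells and pool their trajectories.

    Trajectory ids are re-keyed to be globally unique; a ``cell`` column
    records the source cell.
    """
    rng = np.random.default_rng(seed)
    out = []
    offset = 0
    for c in range(n_cells):
        cell_seed = int(rng.integers(0, 2**31 - 1))
        trajs, _ = sample_trajectories(model, acq, seed=cell_seed)
        if len(trajs):
            trajs = trajs.copy()
            trajs["trajectory_id"] += offset
            trajs["cell"] = c
            offset = int(trajs["trajectory_id"].max()) + 1
            out.append(trajs)
    if not out:
        return pd.DataFrame(
            columns=["trajectory_id", "frame", "x_um", "y_um", "molecule_id", "state_index", "cell"]
        )
    return pd.concat(out, ignore_index=True)


def _integrated_gaussian_patch(
    x_px: float, y_px: float, sigma: float, radius: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixel-integrated 2-D Gaussian (unit volume) on a square patch.

    Pixel i covers [i - 0.5, i + 0.5]; pixel centers sit at integer
    coordinates.  Returns (rows, cols, weights).
    """
    r0 = int(np.floor(y_px)) - radius
    c0 = int(np.floor(x_px)) - radius
    rows = np.arange(r0, r0 + 2 * radius + 1)
    cols = np.arange(c0, c0 + 2 * radius + 1)
    ey = norm.cdf((rows + 0.5 - y_px) / sigma) - norm.cdf((rows - 0.5 - y_px) / sigma)
    ex = norm.cdf((cols + 0.5 - x_px) / sigma) - norm.cdf((cols - 0.5 - x_px) / sigma)
    return rows, cols, np.outer(ey, ex)


def render_movie(
    truth: pd.DataFrame,
    acq: AcquisitionConfig,
    psf_sigma_px: float = 1.0,
    photons_per_spot: float = 300.0,
    background: float = 20.0,
    seed: int = 0,
    wrap: bool = True,
) -> np.ndarray:
    """Render ground-truth molecules into a 16-bit movie stack.

    Each detected molecule is drawn as a pixel-integrated 2-D Gaussian of
    width ``psf_sigma_px`` carrying ``photons_per_spot`` expected counts
    (point-sampled positions: stroboscopic excitation freezes motion, so no
    blur is applied).  Poisson shot noise acts on spot + background.

    With ``wrap=True`` lateral positions are wrapped periodically into the
    field of view; otherwise out-of-field spots are dropped with a warning.
    """
    n_frames = int(truth["frame"].max()) + 1 if len(truth) else acq.n_frames
    n_frames = max(n_frames, acq.n_frames)
    h, w = acq.fov_px
    stack = np.zeros((n_frames, h, w), dtype=float)
    radius = int(np.ceil(4.0 * psf_sigma_px)) + 1

    det = truth[truth["detected"].astype(bool)]
    n_clipped = 0
    for frame, grp in det.groupby("frame"):
        img = stack[int(frame)]
        for x_um, y_um in zip(grp["x_um"].to_numpy(), grp["y_um"].to_numpy()):
            x_px = x_um / acq.pixel_size_um
            y_px = y_um / acq.pixel_size_um
            if wrap:
                x_px = np.mod(x_px, w)
                y_px = np.mod(y_px, h)
            elif not (0 <= x_px < w and 0 <= y_px < h):
                n_clipped += 1
                continue
            rows, cols, patch = _integrated_gaussian_patch(x_px, y_px, psf_sigma_px, radius)
            rmask = (rows >= 0) & (rows < h)
            cmask = (cols >= 0) & (cols < w)
            if rmask.any() and cmask.any():
                img[np.ix_(rows[rmask], cols[cmask])] += (
                    photons_per_spot * patch[np.ix_(rmask, cmask)]
                )
    if n_clipped:
        warnings.warn(f"render_movie: {n_clipped} spot positions outside the field were clipped")

    rng = np.random.default_rng(seed)
    noisy = rng.poisson(stack + background)
    return np.clip(noisy, 0, 65535).astype(np.uint16)


def ground_truth_spectrum(model: SimulationModel, grid: StateGrid) -> DiffusionSpectrum:
    """Place the model's true occupations on their nearest grid nodes.

    Used as the reference in recovery tests.  Raises if any state's
    diffusion coefficient falls outside the grid range.
    """
    occ = np.zeros(grid.diff_coefs.size)
    for s in model.states:
        occ[grid.nearest_diff_coef_index(s.diff_coef)] += s.occupation
    return DiffusionSpectrum(
        diff_coefs=grid.diff_coefs.copy(),
        occupations=occ,
        metadata={"source": "ground_truth"},
    )
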