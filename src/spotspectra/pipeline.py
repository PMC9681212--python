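"""End-to-end orchestration: simulate → track → infer → report.

Each run writes a self-contained directory: a config snapshot, stage
outputs (trajectory tables, per-movie QC, spectra, summaries) and a log.
Re-running with the same seed reproduces all numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import trajio
from .config import AcquisitionConfig, RunConfig, TrackingConfig, save_config
from .detect import detect_spots
from .framefilter import apply_frame_filter, detection_counts, filter_dense_frames, smooth_counts
from .grids import StateGrid
from .likelihood import build_likelihood_matrix
from .link import link_detections, trajectories_to_frame
from .localize import localize_spots
from .report import summarize_spectrum
from .simulate import DiffusiveState, SimulationModel, render_movie, sample_cells, sample_trajectories
from .statearray import infer_spectrum

__all__ = ["track_movie", "run_pipeline", "make_fixtures"]

logger = logging.getLogger(__name__)


def track_movie(
    stack: np.ndarray,
    tracking: TrackingConfig | None = None,
    acq: AcquisitionConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Movie stack → trajectory table plus a QC report.

    Stages: per-frame LLR detection, sub-pixel integrated-Gaussian
    localization, frame-to-frame optimal assignment linking, then the
    dense-frame filter (smoothed detection counts < cutoff) with
    trajectories rebuilt from kept frames only.
    """
    tracking = tracking or TrackingConfig()
    acq = acq or AcquisitionConfig()
    px = acq.pixel_size_um

    detections = []
    for frame in range(tracking.start_frame, stack.shape[0]):
        dets = detect_spots(stack[frame], tracking.detect, frame=frame, pixel_size_um=px)
        dets = localize_spots(stack[frame], dets, tracking.localize, pixel_size_um=px)
        dets = [d for d in dets if d.intensity >= tracking.link.min_intensity]
        detections.extend(dets)

    trajectories = link_detections(detections, tracking.link, pixel_size_um=px)
    table = trajectories_to_frame(trajectories)

    counts = detection_counts(table, n_frames=stack.shape[0])
    kept = filter_dense_frames(counts, tracking.filter)
    filtered = apply_frame_filter(table, kept)

    qc = {
        "n_frames": int(stack.shape[0]),
        "n_detections": len(detections),
        "detections_per_frame": counts.astype(int).tolist(),
        "smoothed_counts": smooth_counts(counts, tracking.filter.smooth_kernel_frames).tolist(),
        "kept_frames": kept.tolist(),
        "n_kept_frames": int(kept.size),
        "n_trajectories_before_filter": int(table["trajectory_id"].nunique()) if len(table) else 0,
        "n_trajectories": int(filtered["trajectory_id"].nunique()) if len(filtered) else 0,
    }
    return filtered, qc


def _pool_trajectory_tables(tables: list[pd.DataFrame]) -> pd.DataFrame:
    pooled = []
    offset = 0
    for i, t in enumerate(tables):
        if len(t) == 0:
            continue
        t = t.copy()
        t["trajectory_id"] = t["trajectory_id"] - t["trajectory_id"].min() + offset
        if "cell" not in t.columns:
            t["cell"] = i
        offset = int(t["trajectory_id"].max()) + 1
        pooled.append(t)
    if not pooled:
        raise ValueError("no trajectories to pool")
    return pd.concat(pooled, ignore_index=True)


def run_pipeline(
    config: RunConfig,
    movies: list[str] | None = None,
    trajectories: list[str] | pd.DataFrame | None = None,
    out_dir: str | Path = "run",
    n_cells: int | None = None,
    model: SimulationModel | None = None,
) -> Path:
    """Run the full analysis and write a run directory.

    Inputs are either movie TIFFs (tracked first), pre-computed trajectory
    tables (tracking skipped), or — when neither is given — a simulation
    (``model`` + ``n_cells``, defaulting to a two-state mixture over 30
    cells).  Stage failures raise with the failing stage named.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, str(out / "config.yaml"))
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        line = f"[{stage}] {msg}"
        logger.info(line)
        log_lines.append(f"{time.strftime('%H:%M:%S')} {line}")

    acq = config.acquisition
    try:
        if movies is not None:
            stage = "track"
            tables = []
            for i, path in enumerate(movies):
                stack = tifffile.imread(path)
                table, qc = track_movie(stack, config.tracking, acq)
                tables.append(table)
                with open(out / f"qc_movie{i}.json", "w") as fh:
                    json.dump(qc, fh)
                log(stage, f"{path}: {qc['n_trajectories']} trajectories")
            pooled = _pool_trajectory_tables(tables)
        elif trajectories is not None:
            stage = "load"
            if isinstance(trajectories, pd.DataFrame):
                pooled = trajio.validate_trajectories(trajectories)
            else:
                pooled = _pool_trajectory_tables(
                    [trajio.read_trajectories(p) for p in trajectories]
                )
            log(stage, f"loaded {pooled['trajectory_id'].nunique()} trajectories")
        else:
            stage = "simulate"
            model = model or SimulationModel()
            pooled = sample_cells(model, acq, n_cells=n_cells or 30, seed=config.seed)
            log(stage, f"simulated {pooled['trajectory_id'].nunique()} trajectories")

        trajio.write_trajectories(
            pooled[["trajectory_id", "frame", "x_um", "y_um"]], str(out / "trajectories.csv")
        )

        stage = "infer"
        grid = StateGrid.from_config(config.grid)
        L = build_likelihood_matrix(pooled, grid, acq)
        bleach = config.inference.bleach_prob_per_frame
        if bleach is None:
            bleach = model.bleach_prob_per_frame if model is not None else 0.0
        n_cells_used = int(pooled["cell"].nunique()) if "cell" in pooled.columns else 1
        spectrum, posterior = infer_spectrum(
            L,
            acq.frame_interval_s,
            acq.focal_depth_um,
            acq.n_frames,
            bleach_prob_per_frame=bleach,
            prior_weight=config.inference.prior_weight,
            max_iter=config.inference.max_iter,
            tol=config.inference.tol,
            defoc_mode=config.inference.defoc_correction,
            metadata={
                "condition": config.condition,
                "replicate": config.replicate,
                "n_cells": n_cells_used,
                "n_trajectories": L.n_trajectories,
                "n_jumps": L.total_jumps,
            },
        )
        spectrum.to_frame().to_csv(out / "spectrum.csv", index=False, float_format="%.9g")
        log(stage, f"{L.n_trajectories} rows, {L.total_jumps} jumps, {posterior.n_iter} sweeps")

        stage = "report"
        summary = summarize_spectrum(
            spectrum,
            condition=config.condition,
            replicate=config.replicate,
            threshold=config.grid.bound_threshold,
        )
        with open(out / "summary.json", "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2)
        log(stage, f"bound_fraction={summary.bound_fraction:.4f}")
    except Exception as err:
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def make_fixtures(seed: int, out_dir: str | Path) -> dict:
    """Generate the bundled small datasets used by tests and examples.

    Writes (a) a two-state trajectory table, (b) a 64×64, 200-frame
    rendered movie, and (c) a digest file so regeneration can be verified
    byte-for-byte.  Returns the digest mapping.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    acq_traj = AcquisitionConfig(n_frames=800)
    model = SimulationModel()
    trajs = sample_cells(model, acq_traj, n_cells=30, seed=seed)
    traj_path = out / "two_state_trajectories.csv"
    trajio.write_trajectories(
        trajs[["trajectory_id", "frame", "x_um", "y_um"]], str(traj_path)
    )

    acq_movie = AcquisitionConfig(fov_px=(64, 64), n_frames=200)
    movie_model = SimulationModel(
        states=[DiffusiveState(0.005, 0.5), DiffusiveState(2.0, 0.5)],
        initial_density_per_frame=5.0,
    )
    _, truth = sample_trajectories(movie_model, acq_movie, seed=seed + 1)
    stack = render_movie(truth, acq_movie, seed=seed + 2)
    movie_path = out / "two_state_movie.tif"
    tifffile.imwrite(str(movie_path), stack)
    truth_path = out / "two_state_movie_truth.csv"
    truth.to_csv(truth_path, index=False, float_format="%.6f")

    digests = {
        "seed": seed,
        "two_state_trajectories.csv": _sha256(traj_path),
        "two_state_movie.tif": _sha256(movie_path),
        "two_state_movie_truth.csv": _sha256(truth_path),
    }
    with open(out / "digests.json", "w") as fh:
        json.dump(digests, fh, indent=2)
    return digests
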