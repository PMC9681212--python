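"""Render a movie from simulated ground truth and track it back.

Runs the full image path: pixel-integrated Gaussian spots with Poisson
noise, LLR detection (k=1, w=15, t=18), sub-pixel integrated-Gaussian
localization, optimal-assignment linking (1 µm search radius, no gap
closing), and the smoothed dense-frame filter. Prints detection counts and
the localization accuracy against ground truth.
"""

import numpy as np

from spotspectra import (
    AcquisitionConfig,
    DiffusiveState,
    SimulationModel,
    render_movie,
    sample_trajectories,
    track_movie,
)

acq = AcquisitionConfig(fov_px=(64, 64), n_frames=200)
model = SimulationModel(
    states=[DiffusiveState(0.005, 0.5), DiffusiveState(2.0, 0.5)],
    initial_density_per_frame=5.0,
)
trajs_true, truth = sample_trajectories(model, acq, seed=11)
stack = render_movie(truth, acq, photons_per_spot=500, background=20.0, seed=12)

table, qc = track_movie(stack)
print(f"movie: {stack.shape[0]} frames of {stack.shape[1]}×{stack.shape[2]} px")
print(f"detections: {qc['n_detections']}  (true detectable positions: {int(truth['detected'].sum())})")
print(f"trajectories: {qc['n_trajectories']}  kept frames: {qc['n_kept_frames']}/{qc['n_frames']}")

# localization accuracy: nearest true in-focus molecule per detection
px = acq.pixel_size_um
errs = []
det = truth[truth["detected"]]
for frame, g in table.groupby("frame"):
    tr = det[det["frame"] == frame]
    if not len(tr):
        continue
    tx = np.mod(tr["x_um"].to_numpy() / px, 64) * px
    ty = np.mod(tr["y_um"].to_numpy() / px, 64) * px
    for x, y in zip(g["x_um"], g["y_um"]):
        errs.append(np.min(np.hypot(tx - x, ty - y)))
errs = np.array(errs)
print(f"median localization error: {np.median(errs) * 1000:.1f} nm "
      f"(photon-limited; the σ grid of the inference absorbs it)")
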