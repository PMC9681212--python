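"""Infer a diffusion spectrum and bound fraction from pooled trajectories.

Simulates three replicates of 30 cells of a 40% bound / 60% mobile
(D = 3 µm²/s) factor, evaluates the RBME likelihood of every trajectory
over the (D, σ) state grid, runs the variational occupation inference,
applies the defocalization correction, and prints the summary statistics
with and without the correction — showing why the correction matters.
"""

from spotspectra import (
    AcquisitionConfig,
    DiffusiveState,
    SimulationModel,
    StateGrid,
    bound_fraction,
    build_likelihood_matrix,
    infer_spectrum,
    moving_mean_D,
    moving_peak_D,
    sample_cells,
)

acq = AcquisitionConfig(n_frames=800)
grid = StateGrid()
model = SimulationModel(states=[DiffusiveState(0.005, 0.4), DiffusiveState(3.0, 0.6)])

pooled = sample_cells(model, acq, n_cells=90, seed=1)
L = build_likelihood_matrix(pooled, grid, acq)
print(f"pooled: {L.n_trajectories} trajectories, {L.total_jumps} jumps "
      f"({L.n_dropped} single detections dropped)")

for mode, label in [("slab_reflect", "with defocalization correction"),
                    ("none", "raw (no correction)")]:
    spectrum, post = infer_spectrum(
        L,
        acq.frame_interval_s,
        acq.focal_depth_um,
        acq.n_frames,
        bleach_prob_per_frame=model.bleach_prob_per_frame,
        defoc_mode=mode,
    )
    bf = bound_fraction(spectrum, grid.bound_threshold)
    print(f"{label}:")
    print(f"  bound fraction (D < 0.1 µm²/s): {bf:.3f}   [truth: 0.400]")
    print(f"  peak moving D:  {moving_peak_D(spectrum):.2f} µm²/s   [truth: 3.0]")
    print(f"  mean moving D:  {moving_mean_D(spectrum):.2f} µm²/s")
print("Raw occupations over-count slow molecules because fast ones defocalize")
print("after a few jumps; dividing by the expected jumps per molecule of each")
print("state and renormalizing recovers the molecule proportions.")
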