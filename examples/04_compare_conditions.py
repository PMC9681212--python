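"""Compare two conditions across replicates, bar-plot style.

Emulates a binding perturbation (e.g. overexpressing a dimerization
partner): condition A has 25% bound occupation, condition B 50%. Each
condition is measured as three independent replicates of 30 cells; the
printed table is the usual replicate-dots-plus-mean summary, and the
difference of means recovers the induced change.
"""

from spotspectra import (
    AcquisitionConfig,
    DiffusiveState,
    SimulationModel,
    StateGrid,
    aggregate_replicates,
    build_likelihood_matrix,
    compare_conditions,
    infer_spectrum,
    sample_cells,
    summarize_spectrum,
)

acq = AcquisitionConfig(n_frames=800)
grid = StateGrid()


def measure(condition, p_bound, base_seed):
    summaries = []
    for rep in range(3):
        model = SimulationModel(
            states=[DiffusiveState(0.005, p_bound), DiffusiveState(3.0, 1 - p_bound)]
        )
        cells = sample_cells(model, acq, n_cells=30, seed=base_seed + rep)
        L = build_likelihood_matrix(cells, grid, acq)
        spectrum, _ = infer_spectrum(
            L, acq.frame_interval_s, acq.focal_depth_um, acq.n_frames,
            bleach_prob_per_frame=model.bleach_prob_per_frame,
            metadata={"n_cells": 30, "n_trajectories": L.n_trajectories,
                      "n_jumps": L.total_jumps},
        )
        summaries.append(
            summarize_spectrum(spectrum, condition=condition, replicate=f"rep{rep + 1}")
        )
    return aggregate_replicates(summaries)


parental = measure("parental", 0.25, base_seed=100)
overexp = measure("overexpression", 0.50, base_seed=200)

for g in (parental, overexp):
    bfs = ", ".join(f"{s.bound_fraction:.3f}" for s in g.replicates)
    print(f"{g.condition}: bound fraction replicates [{bfs}] "
          f"mean {g.mean_bound_fraction:.3f}")

out = compare_conditions([parental, overexp])
d = out["differences"]
row = d[(d.condition_a == "overexpression") & (d.condition_b == "parental")
        & (d.statistic == "bound_fraction")]
print(f"bound-fraction increase (overexpression − parental): "
      f"{row['difference'].iloc[0]:+.3f}   [induced: +0.250]")
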