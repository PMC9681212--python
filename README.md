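# spotspectra

Fast single-particle tracking (fSPT) analysis for nuclear proteins:
simulate multi-state diffusing molecules imaged through a thin focal slab,
track rendered movies (detection → sub-pixel localization → linking →
dense-frame filtering), and infer the **diffusion spectrum** — the
proportion of molecules as a function of diffusion coefficient — with a
localization-error- and defocalization-aware Bayesian state array. The
headline outputs are the **bound fraction** (occupation at
D < 0.1 µm²/s, read as chromatin-associated molecules) and the peak/mean
diffusion coefficient of the moving population, aggregated over
biological replicates per condition.

It is written for experiments like live-cell tracking of HaloTag-labeled
transcription factors at ~182 Hz (5.48 ms frames, 0.16 µm pixels, 0.7 µm
detection depth, ~10 detected molecules per frame): all of those
processing parameters are the library defaults.

## The model

Each observed trajectory is scored under regular Brownian motion with
Gaussian localization error (RBME): the vector of n successive jumps along
one axis is zero-mean multivariate normal with covariance

```
C = 2DΔt·I + σ²·T,   T = tridiag(−1, 2, −1)
```

(diagonal 2DΔt + 2σ², off-diagonal −σ²). Likelihoods are evaluated over a
dense grid of states — 101 diffusion coefficients spanning 0.01–100 µm²/s
(geometric) × 17 localization errors spanning 0–0.08 µm — and state
occupations are inferred by variational Bayes for a Dirichlet mixture,
with each trajectory weighted by its jump count. Because fast molecules
leave the 0.7 µm detection slab after a few frames, raw occupations
over-weight slow states; occupations are divided by the expected number
of observed jumps per molecule of each state (computed in closed form for
the bounded axial geometry, including slab re-entries and photobleaching)
and renormalized. Marginalizing localization error yields the diffusion
spectrum.

## Worked example

`examples/03_diffusion_spectrum.py` simulates three replicates of 30
cells of a 40% bound / 60% mobile (D = 3 µm²/s) factor under the default
acquisition conditions, then infers the spectrum with and without the
defocalization correction:

```
pooled: 1704 trajectories, 23349 jumps (558 single detections dropped)
with defocalization correction:
  bound fraction (D < 0.1 µm²/s): 0.398   [truth: 0.400]
  peak moving D:  3.02 µm²/s   [truth: 3.0]
  mean moving D:  3.02 µm²/s
raw (no correction):
  bound fraction (D < 0.1 µm²/s): 0.708   [truth: 0.400]
  peak moving D:  3.02 µm²/s   [truth: 3.0]
  mean moving D:  2.98 µm²/s
```

The corrected bound fraction matches the simulated truth to the third
decimal at this sample size, while the uncorrected one overestimates
binding by ~0.3 — slow molecules are observed for ~46 jumps each before
bleaching, mobile ones for only ~12.

The other examples cover the remaining capabilities: `01` the simulator's
observed-trajectory statistics, `02` movie rendering and tracking, `04`
replicate aggregation and condition comparison, `05` per-cell naive
occupation estimates.

## Command line

A thin CLI mirrors the pipeline stages:

```
spotspectra simulate --seed 1 --n-cells 30 --out sim/
spotspectra track    --movie movie.tif --config cfg.yaml --out trajs.csv
spotspectra infer    --trajs trajs.csv --out run/
spotspectra report   --spectrum run/spectrum.csv --out summary.json
spotspectra run      --config cfg.yaml --seed 1 --out run/
```

`run` accepts movies (tracked first), trajectory CSVs (tracking skipped),
or nothing (simulation). Each run directory holds the config snapshot,
trajectory table, spectrum CSV, per-movie QC JSON and summary JSON;
re-running with the same seed reproduces every number.

Trajectory tables are plain CSV (`trajectory_id, frame, x_um, y_um`) with
strictly consecutive frames per trajectory (no gap closing anywhere in
the pipeline).

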