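# Methods

## Scope and model

`spotspectra` analyzes fast single-particle tracking (fSPT) of sparsely
labeled nuclear proteins: movies taken at ~182 Hz (5.48 ms frames) under
stroboscopic HiLo illumination, tracked into short trajectories, from which
the distribution of diffusion coefficients — the *diffusion spectrum* — is
inferred. The headline statistic is the **bound fraction**: the summed
occupation of states with D < 0.1 µm²/s, read as chromatin-associated
molecules. The moving population is summarized by its peak (grid argmax)
and occupation-weighted mean diffusion coefficient.

### Observation model (RBME)

Each trajectory is modeled as regular Brownian motion with normally
distributed localization error. For a trajectory with n jumps at frame
interval Δt, the per-axis jump vector is zero-mean multivariate normal
with tridiagonal covariance

    C = 2DΔt·I + σ²·T,   T = tridiag(−1, 2, −1),

i.e. diagonal 2DΔt + 2σ² and off-diagonal −σ² (consecutive jumps share one
noisy endpoint). T's eigenvectors are discrete sines with eigenvalues
λ_k = 2 − 2cos(kπ/(n+1)), so evaluating a trajectory against the whole
(D, σ) grid costs one orthogonal transform of its jumps plus diagonal
Gaussian terms per state — this is what makes the dense grid practical.
x and y are independent; the likelihood is their product. The covariance
algebra is pinned by a closed-form two-jump example, a Monte-Carlo sample
covariance, and a dense `multivariate_normal` cross-check in the tests.

### State grid and occupation inference

States live on a 101-node geometric D grid spanning 0.01–100 µm²/s crossed
with 17 localization-error nodes spanning 0–0.08 µm. Grid resolution is a
runtime/beyond-resolution tradeoff (nodes are ~10% apart in D, below the
statistical resolution of the data) and is exposed in `GridConfig`.

Occupations are inferred by mean-field variational inference for a mixture
over grid states with a symmetric Dirichlet prior: iterate per-trajectory
responsibilities ∝ row-likelihood × exp(ψ(α_k)), then the concentration
update α = α₀ + Σ_t n_t r_t, with each trajectory weighted by its jump
count n_t. Iteration stops when the posterior-mean occupations move less
than 1e-8 (default cap 1000 sweeps; in practice occupations are stable to
3 decimals after ~500). Initialization is uniform, so the procedure is
deterministic and invariant to trajectory order. The prior weight defaults
to the jump count of one median-length trajectory spread uniformly over
states — weak against any realistic pooled dataset; doubling it moves the
recovered bound fraction by <0.02 in the tests.

Jump-count weighting makes raw occupations proportions of *observed
jumps*, not molecules; the defocalization correction below converts
between the two. The pairing of these two choices is validated end to end
by parameter recovery against simulation truth.

### Defocalization

Molecules are detected only within an axial slab of depth dz = 0.7 µm, so
fast molecules contribute fewer observed jumps per molecule and raw
occupations over-weight slow states. Two deterministic quantities handle
this:

1. `defocalization_survival(D, Δt, dz, n)` — the probability that a
   molecule starting uniformly inside the slab is inside at all of the
   first n frame times, computed with a discretized absorbing-slab
   propagator (axial step dz/100; discretization error ~1e-4, verified
   against 10⁶-walker Monte Carlo).
2. `expected_observed_jumps(D, Δt, dz, N, r)` — the expected *total*
   number of observed jumps per molecule over an N-frame movie, counting
   re-entries into the slab and a per-frame retention r = 1 − bleaching
   probability. Because the observed-trajectory construction does no gap
   closing, every re-entry starts a new trajectory; its jumps still belong
   to the same molecule and must be counted. This is evaluated in closed
   form in the cosine eigenbasis of reflected Brownian motion on the
   bounded axial domain (±5·dz) that the simulator uses, and is also
   Monte-Carlo validated.

The correction divides each state's occupation by the expected jumps per
molecule at that state's D and renormalizes. The first-segment-only form
E_D = Σ_n rⁿ·survival(D, n) is available as `defoc_correction="absorbing"`;
with single-step bleaching and long movies it underestimates mobile-state
jump counts severalfold (re-entries dominate), which is why the
reflecting-domain form is the default. With bound-state expected jumps
≈46 versus ≈12 at D = 3 µm²/s (0.02 bleaching, 800 frames), the raw bound
fraction of a 40%-bound mixture reads ≈0.73 and corrects to 0.40 ± 0.03.

For real data the retention rate is not known a priori; it can be
estimated from the length distribution of slow trajectories (bleaching is
the only thing that ends them) and passed via
`InferenceConfig.bleach_prob_per_frame`.

### Per-cell naive estimate

With tens of trajectories per cell a full posterior is not meaningful, so
per-cell behavior is summarized by the jump-count-weighted average of
row-normalized RBME likelihoods (`naive_cell_occupations`), matching how
per-cell likelihood heat maps are usually displayed. For a large
single-state cell its D-marginal mode coincides with the state-array mode
(tested).

## Tracking

Detection scores each pixel with a generalized log-likelihood ratio for a
pixel-integrated Gaussian spot (width k = 1 px) versus flat background
over a 15×15 window: T = −(N/2)·ln(1 − r²) with r the normalized
correlation against the mean-subtracted template. Candidates are window
local maxima with T > 18; at that threshold the per-pixel null tail is
~1e-9, and pure-noise frames produce essentially no false positives.

Localization fits amplitude, background and center of a pixel-integrated
Gaussian (σ fixed at 1 px) on a 9×9 window by damped (0.3),
ridge-regularized (1e-3) Gauss–Newton, at most 20 iterations. With a 0.3
damping factor the contraction is 0.7 per iteration, so convergence is
declared when the damped center update falls below 1e-3 px (0.16 nm) —
noiseless sub-pixel spots are recovered to ~0.002 px. Fits that do not
converge (e.g. flat windows) keep the integer pixel position and are
flagged; windows clipped by the frame edge are dropped.

Linking solves, per consecutive frame pair, the globally optimal
one-to-one assignment minimizing summed squared distances with links
beyond 1.0 µm forbidden (scipy's Hungarian solver with a large forbidden
cost; behavior pinned against exhaustive enumeration). There is no gap
closing, and frames with more than 7 detections are excluded from linking
entirely. The dense-frame filter then smooths per-frame detection counts
with a centered 21-frame uniform kernel (truncated at the edges) and keeps
frames with smoothed counts strictly below 7; trajectories are rebuilt
from kept frames, splitting at removals. Frames whose smoothed count is
exactly 7 are removed; `FrameFilterConfig.keep_strictly_below` records the
choice.

## Simulator

The simulator produces what the analysis assumes, plus the known
real-data pathologies it corrects for: a small set of diffusive states
with fixed occupations, 3-D Brownian motion (per-axis increment variance
2DΔt), i.i.d. Gaussian localization error (default σ = 0.035 µm — the
instrument's error is not published; 20–50 nm is typical for this photon
budget, and the default sits in that range and is a config field),
detection only within |z| ≤ dz/2, single-step photobleaching (default
0.02/frame, giving bleach-limited bound trajectories of ~49 jumps over
800-frame movies), and ~10 molecules present in the first frames.

Axial motion diffuses freely with reflection at ±5·dz; molecules start
uniformly inside the slab, so everything is detected at frame 0 — matching
sparse-labeling acquisitions that track from the first frame. A molecule
leaving and re-entering the slab is emitted as a new observed trajectory
(no gap closing downstream). Lateral positions are unbounded in trajectory
output (wrapping would inject fake FOV-sized jumps); movie rendering wraps
them periodically into the field so spot density stays stationary. Spots
are rendered as pixel-integrated Gaussians with Poisson noise on spot plus
background, no motion blur (stroboscopic pulses freeze motion by design).
State switching within a trajectory is off by default — the inference
assumes one state per trajectory — and available for robustness tests.

What the simulator does not emulate: non-uniform HiLo illumination,
EM-CCD excess noise, dye blinking/photophysics beyond single-step
bleaching, nuclear boundaries and chromatin-density heterogeneity, and
state switching in the default configuration. Passing recovery tests
therefore demonstrate correctness of the estimator under its own model
assumptions, not robustness to every real-data deviation.

## Study conditions used in tests

Recovery tests pool 3 replicates × 30 cells (the acquisition protocol
collects ≥20 movies per replicate on 3 days) at ~10 molecules per cell and
800 frames, giving ~2×10⁴ pooled jumps for mixtures with a substantial
bound population. At these sizes the recovered bound fraction carries a
sampling spread of ±0.01–0.02 and a positive bias ≤0.03 (short mobile
trajectories are genuinely ambiguous with bound states at high
localization error — the D–σ degeneracy of one-jump data), comfortably
within the ±0.05 recovery band asserted by the acceptance tests across
bound occupations 0.1–0.7 and free D 1–10 µm²/s. The movie-tracking
suite uses 200-frame, 64–128 px movies at 500 photons/spot over a
20-count background so it runs in seconds per movie.

## Numerical choices and degenerate inputs

- Variances on the (D=0.01, σ=0) grid corner are well above the 1e-14
  floor; the floor only guards user-supplied degenerate grids.
- Likelihood rows are normalized in log space (logsumexp).
- Survival tables and sine bases are cached per (D, n) and n.
- Trajectories with fewer than one jump are dropped from inference and
  counted (`n_dropped`).
- Ties in `moving_peak_D` break toward smaller D.
- Empty datasets, non-normalized rows, occupations not summing to one,
  and thresholds outside the grid raise `ValueError` with messages.

## Known limitations

- Occupations carry no posterior uncertainty intervals; replicate spread
  (three independent simulated or measured replicates) is the intended
  error indicator.
- The defocalization correction assumes the axial geometry of the
  simulator (uniform start in slab, bounded domain). Real nuclei have
  finite, variable thickness; the correction's sensitivity to the domain
  half-width enters only through re-entry counts.
- No anomalous diffusion, no motion-blur covariance (justified by
  stroboscopic excitation), no within-trajectory state switching in the
  likelihood.
- Spectra report proportions, not absolute molecule numbers.
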