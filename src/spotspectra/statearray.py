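"""Posterior-mean state occupations over the grid (the "state array").

Trajectories are modeled as draws from a mixture over the (D, σ) grid with
a symmetric Dirichlet prior on the occupation vector.  Mean-field
variational inference alternates between per-trajectory responsibilities
and the Dirichlet concentration update, with each trajectory weighted by
its jump count so occupations report proportions of molecules' observed
jumps.  Dividing by the expected number of observed jumps per molecule of
each state (defocalization correction) then converts jump proportions into
molecule proportions; marginalizing σ yields the diffusion spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma

from .defoc import expected_jumps_absorbing, expected_observed_jumps
from .grids import DiffusionSpectrum, StateGrid
from .likelihood import LikelihoodMatrix

__all__ = [
    "OccupationPosterior",
    "infer_occupations",
    "correct_defocalization",
    "defocalization_weights",
    "marginalize_sigma",
    "infer_spectrum",
]


@dataclass
class OccupationPosterior:
    """Variational posterior over grid-state occupations.

    ``concentrations`` are the Dirichlet parameters; ``occupations`` the
    posterior mean (normalized concentrations), flattened D-major to match
    :class:`~spotspectra.likelihood.LikelihoodMatrix` columns.
    """

    grid: StateGrid
    concentrations: np.ndarray
    occupations: np.ndarray
    n_iter: int
    converged: bool
    metadata: dict = field(default_factory=dict)

    def occupations_2d(self) -> np.ndarray:
        return self.occupations.reshape(self.grid.shape)


def infer_occupations(
    L: LikelihoodMatrix,
    prior_weight: float | None = None,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> OccupationPosterior:
    """Mean-field variational inference of state occupations.

    Parameters
    ----------
    L
        Row-normalized likelihood matrix.
    prior_weight
        Total concentration of the symmetric Dirichlet prior, spread
        uniformly over states.  Defaults to the weight of one
        median-length trajectory — weak relative to the pooled data.
    max_iter, tol
        Stop when the largest absolute change in posterior-mean occupation
        falls below ``tol``, or after ``max_iter`` sweeps.

    Deterministic: responsibilities start from uniform occupations.
    """
    if L.n_trajectories == 0:
        raise ValueError("likelihood matrix is empty")
    row_sums = L.values.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-6):
        raise ValueError("likelihood rows must be normalized to sum to 1")
    if prior_weight is None:
        prior_weight = float(np.median(L.jump_counts))
    if prior_weight <= 0:
        raise ValueError("prior_weight must be positive")

    K = L.values.shape[1]
    weights = L.jump_counts.astype(float)
    alpha0 = prior_weight / K
    alpha = np.full(K, alpha0 + weights.sum() / K)
    occ = alpha / alpha.sum()

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step: responsibilities ∝ likelihood × exp(ψ(α_k) - ψ(Σα)).
        log_w = digamma(alpha)  # common ψ(Σα) cancels in the row softmax
        log_w -= log_w.max()
        R = L.values * np.exp(log_w)[None, :]
        R /= R.sum(axis=1, keepdims=True)
        # M-step: concentration = prior + jump-weighted responsibilities.
        alpha = alpha0 + weights @ R
        new_occ = alpha / alpha.sum()
        delta = np.max(np.abs(new_occ - occ))
        occ = new_occ
        if delta < tol:
            converged = True
            break

    return OccupationPosterior(
        grid=L.grid,
        concentrations=alpha,
        occupations=occ,
        n_iter=n_iter,
        converged=converged,
        metadata={
            "prior_weight": prior_weight,
            "n_trajectories": L.n_trajectories,
            "n_jumps": L.total_jumps,
        },
    )


def defocalization_weights(
    grid: StateGrid,
    frame_interval_s: float,
    focal_depth_um: float,
    n_frames: int,
    bleach_prob_per_frame: float = 0.0,
    mode: str = "slab_reflect",
) -> np.ndarray:
    """Expected observed jumps per molecule for every D node of the grid.

    ``mode='slab_reflect'`` (default) counts re-entries into the detection
    slab on the bounded axial domain, with photobleaching retention;
    ``mode='absorbing'`` counts only the first observed segment
    (E_D = Σ_n r^n · survival(D, n), truncated at the movie length).
    """
    retention = 1.0 - bleach_prob_per_frame
    if mode == "slab_reflect":
        fn = lambda d: expected_observed_jumps(
            d, frame_interval_s, focal_depth_um, n_frames, retention
        )
    elif mode == "absorbing":
        fn = lambda d: expected_jumps_absorbing(
            d, frame_interval_s, focal_depth_um, n_frames, retention
        )
    else:
        raise ValueError(f"unknown defocalization mode {mode!r}")
    return np.array([fn(float(d)) for d in grid.diff_coefs])


def correct_defocalization(
    posterior: OccupationPosterior,
    expected_jumps: np.ndarray,
) -> OccupationPosterior:
    """Convert jump-proportion occupations into molecule proportions.

    Divides each state's occupation by the expected number of observed
    jumps per molecule of that state's D (a vector over the D grid), then
    renormalizes.  Fast states — whose molecules contribute few jumps
    before defocalizing — are up-weighted relative to the raw occupations.
    """
    import warnings

    E = np.asarray(expected_jumps, dtype=float)
    if E.shape != posterior.grid.diff_coefs.shape:
        raise ValueError("expected_jumps must have one entry per D grid node")
    if np.any(E < 1e-12):
        warnings.warn("expected jump counts floored at 1e-12")
        E = np.maximum(E, 1e-12)
    occ2d = posterior.occupations_2d() / E[:, None]
    occ = occ2d.ravel()
    occ = occ / occ.sum()
    return OccupationPosterior(
        grid=posterior.grid,
        concentrations=posterior.concentrations.copy(),
        occupations=occ,
        n_iter=posterior.n_iter,
        converged=posterior.converged,
        metadata={**posterior.metadata, "defocalization_corrected": True},
    )


def marginalize_sigma(posterior: OccupationPosterior, metadata: dict | None = None) -> DiffusionSpectrum:
    """Sum occupations over the localization-error axis: the diffusion spectrum."""
    occ = posterior.occupations_2d().sum(axis=1)
    occ = occ / occ.sum()
    md = dict(posterior.metadata)
    if metadata:
        md.update(metadata)
    return DiffusionSpectrum(
        diff_coefs=posterior.grid.diff_coefs.copy(), occupations=occ, metadata=md
    )


def infer_spectrum(
    L: LikelihoodMatrix,
    frame_interval_s: float,
    focal_depth_um: float,
    n_frames: int,
    bleach_prob_per_frame: float = 0.0,
    prior_weight: float | None = None,
    max_iter: int = 1000,
    tol: float = 1e-8,
    defoc_mode: str = "slab_reflect",
    metadata: dict | None = None,
) -> tuple[DiffusionSpectrum, OccupationPosterior]:
    """Convenience wrapper: infer, correct for defocalization, marginalize."""
    post = infer_occupations(L, prior_weight=prior_weight, max_iter=max_iter, tol=tol)
    if defoc_mode != "none":
        E = defocalization_weights(
            L.grid,
            frame_interval_s,
            focal_depth_um,
            n_frames,
            bleach_prob_per_frame,
            mode=defoc_mode,
        )
        post = correct_defocalization(post, E)
    spectrum = marginalize_sigma(post, metadata=metadata)
    return spectrum, post
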