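"""Plotting helpers: diffusion spectra with shaded bound fractions, and
per-cell likelihood heat maps."""

from __future__ import annotations

import numpy as np

from .grids import DiffusionSpectrum

__all__ = ["plot_spectrum", "plot_cell_likelihoods"]


def plot_spectrum(
    spectrum: DiffusionSpectrum,
    ax=None,
    threshold: float = 0.1,
    color: str = "C0",
    label: str | None = None,
    shade: bool = True,
):
    """Occupation vs diffusion coefficient on a log axis.

    The region below the bound threshold is shaded; the shaded area is the
    bound fraction.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    d = spectrum.diff_coefs
    occ = spectrum.occupations
    ax.plot(d, occ, color=color, label=label)
    if shade:
        bound = d < threshold
        ax.fill_between(d[bound], 0, occ[bound], color=color, alpha=0.3)
        ax.axvline(threshold, color="0.5", lw=0.8, ls="--")
    ax.set_xscale("log")
    ax.set_xlabel("diffusion coefficient (µm²/s)")
    ax.set_ylabel("occupation")
    ax.set_ylim(bottom=0)
    if label:
        ax.legend(frameon=False)
    return ax


def plot_cell_likelihoods(cell_marginals: np.ndarray, diff_coefs: np.ndarray, ax=None):
    """Heat map of per-cell naive D-marginals (one row per cell)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    m = np.asarray(cell_marginals)
    ax.imshow(
        m,
        aspect="auto",
        origin="lower",
        extent=(np.log10(diff_coefs[0]), np.log10(diff_coefs[-1]), 0, m.shape[0]),
        cmap="viridis",
    )
    ax.set_xlabel("log10 diffusion coefficient (µm²/s)")
    ax.set_ylabel("cell")
    return ax
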