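"""State grids and diffusion spectra.

The inference operates on a dense two-dimensional grid of candidate states:
diffusion coefficients D (geometric sequence, default 0.01-100 µm²/s) by
localization errors σ (arithmetic sequence, default 0-0.08 µm).  A
*diffusion spectrum* is the occupation vector marginalized over σ: the
proportion of molecules as a function of D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StateGrid", "DiffusionSpectrum"]


@dataclass
class StateGrid:
    """Two-dimensional grid of candidate (D, σ) states.

    Attributes
    ----------
    diff_coefs
        Strictly increasing diffusion coefficients, µm²/s.
    loc_errors
        Strictly increasing localization error magnitudes, µm.
    bound_threshold
        Diffusion coefficient below which a state is scored as immobile
        (chromatin-bound), µm²/s.
    """

    diff_coefs: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.01, 100.0, 101)
    )
    loc_errors: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 0.08, 17))
    bound_threshold: float = 0.1

    def __post_init__(self) -> None:
        self.diff_coefs = np.asarray(self.diff_coefs, dtype=float)
        self.loc_errors = np.asarray(self.loc_errors, dtype=float)
        if self.diff_coefs.ndim != 1 or self.diff_coefs.size < 2:
            raise ValueError("diff_coefs must be a 1-D array with >= 2 nodes")
        if np.any(np.diff(self.diff_coefs) <= 0):
            raise ValueError("diff_coefs must be strictly increasing")
        if np.any(np.diff(self.loc_errors) <= 0):
            raise ValueError("loc_errors must be strictly increasing")
        if not (self.diff_coefs[0] < self.bound_threshold < self.diff_coefs[-1]):
            raise ValueError("bound_threshold must lie inside the D range")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.diff_coefs.size, self.loc_errors.size)

    @property
    def n_states(self) -> int:
        return self.diff_coefs.size * self.loc_errors.size

    def nearest_diff_coef_index(self, d: float) -> int:
        """Index of the grid node closest to ``d`` in log-D distance."""
        if d < self.diff_coefs[0] or d > self.diff_coefs[-1]:
            raise ValueError(
                f"diffusion coefficient {d} outside grid range "
                f"[{self.diff_coefs[0]}, {self.diff_coefs[-1]}]"
            )
        return int(np.argmin(np.abs(np.log(self.diff_coefs) - np.log(d))))

    @classmethod
    def from_config(cls, cfg) -> "StateGrid":
        return cls(
            diff_coefs=np.geomspace(cfg.d_min, cfg.d_max, cfg.n_diff_coefs),
            loc_errors=np.linspace(cfg.sigma_min, cfg.sigma_max, cfg.n_loc_errors),
            bound_threshold=cfg.bound_threshold,
        )


@dataclass
class DiffusionSpectrum:
    """Occupation (proportion of molecules) per diffusion-coefficient node.

    Occupations are non-negative and sum to one; metadata carries sample
    sizes and the condition label so downstream summaries can report them.
    """

    diff_coefs: np.ndarray
    occupations: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.diff_coefs = np.asarray(self.diff_coefs, dtype=float)
        self.occupations = np.asarray(self.occupations, dtype=float)
        if self.diff_coefs.shape != self.occupations.shape:
            raise ValueError("diff_coefs and occupations must have equal length")
        if np.any(self.occupations < -1e-12):
            raise ValueError("occupations must be non-negative")
        total = self.occupations.sum()
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"occupations must sum to 1 (got {total})")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"diff_coef_um2_s": self.diff_coefs, "occupation": self.occupations}
        )
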