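"""Summary statistics from diffusion spectra and replicate aggregation.

The headline quantity is the bound fraction: total occupation at diffusion
coefficients below 0.1 µm²/s, interpreted as immobile, chromatin-associated
molecules.  The moving population (D >= threshold) is summarized by its
peak (grid argmax) and occupation-weighted mean diffusion coefficient.
Replicates are averaged arithmetically; conditions are compared by
differences of replicate means (no hypothesis testing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import DiffusionSpectrum

__all__ = [
    "DynamicsSummary",
    "ReplicateSummary",
    "bound_fraction",
    "moving_peak_D",
    "moving_mean_D",
    "summarize_spectrum",
    "aggregate_replicates",
    "compare_conditions",
]

DEFAULT_BOUND_THRESHOLD = 0.1


def _check_threshold(spectrum: DiffusionSpectrum, threshold: float) -> None:
    d = spectrum.diff_coefs
    if not (d[0] <= threshold <= d[-1]):
        raise ValueError(
            f"threshold {threshold} outside spectrum D range [{d[0]}, {d[-1]}]"
        )


def bound_fraction(
    spectrum: DiffusionSpectrum, threshold: float = DEFAULT_BOUND_THRESHOLD
) -> float:
    """Total occupation at grid nodes with D strictly below ``threshold``."""
    _check_threshold(spectrum, threshold)
    return float(spectrum.occupations[spectrum.diff_coefs < threshold].sum())


def moving_peak_D(
    spectrum: DiffusionSpectrum, threshold: float = DEFAULT_BOUND_THRESHOLD
) -> float:
    """Grid D with the largest occupation among moving nodes (D >= threshold).

    Ties break toward the smaller diffusion coefficient.
    """
    _check_threshold(spectrum, threshold)
    moving = spectrum.diff_coefs >= threshold
    occ = spectrum.occupations[moving]
    if occ.sum() <= 0:
        raise ValueError("no moving mass: all occupation below the bound threshold")
    return float(spectrum.diff_coefs[moving][int(np.argmax(occ))])


def moving_mean_D(
    spectrum: DiffusionSpectrum, threshold: float = DEFAULT_BOUND_THRESHOLD
) -> float:
    """Occupation-weighted arithmetic mean D over moving nodes (D >= threshold)."""
    _check_threshold(spectrum, threshold)
    moving = spectrum.diff_coefs >= threshold
    occ = spectrum.occupations[moving]
    total = occ.sum()
    if total <= 0:
        raise ValueError("no moving mass: all occupation below the bound threshold")
    return float((spectrum.diff_coefs[moving] * occ).sum() / total)


@dataclass
class DynamicsSummary:
    """Bound fraction and moving-population statistics for one replicate."""

    condition: str
    replicate: str
    bound_fraction: float
    peak_D_moving: float | None
    mean_D_moving: float | None
    n_cells: int = 0
    n_trajectories: int = 0
    n_jumps: int = 0

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "replicate": self.replicate,
            "bound_fraction": self.bound_fraction,
            "peak_D_moving": self.peak_D_moving,
            "mean_D_moving": self.mean_D_moving,
            "n_cells": self.n_cells,
            "n_trajectories": self.n_trajectories,
            "n_jumps": self.n_jumps,
        }


def summarize_spectrum(
    spectrum: DiffusionSpectrum,
    condition: str = "condition",
    replicate: str = "rep1",
    threshold: float = DEFAULT_BOUND_THRESHOLD,
) -> DynamicsSummary:
    """Compute all summary statistics for one spectrum.

    Peak and mean moving D are ``None`` when all mass is bound.
    """
    bf = bound_fraction(spectrum, threshold)
    try:
        peak = moving_peak_D(spectrum, threshold)
        mean = moving_mean_D(spectrum, threshold)
    except ValueError:
        peak = None
        mean = None
    md = spectrum.metadata
    return DynamicsSummary(
        condition=condition,
        replicate=replicate,
        bound_fraction=bf,
        peak_D_moving=peak,
        mean_D_moving=mean,
        n_cells=int(md.get("n_cells", 0)),
        n_trajectories=int(md.get("n_trajectories", 0)),
        n_jumps=int(md.get("n_jumps", 0)),
    )


@dataclass
class ReplicateSummary:
    """Per-replicate summaries for one condition plus their means."""

    condition: str
    replicates: list[DynamicsSummary] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("at least one replicate is required")
        labels = {s.condition for s in self.replicates}
        if labels != {self.condition}:
            raise ValueError(f"mixed condition labels: {sorted(labels)}")

    def _mean(self, attr: str) -> float | None:
        vals = [getattr(s, attr) for s in self.replicates]
        if any(v is None for v in vals):
            return None
        return float(np.mean(vals))

    @property
    def mean_bound_fraction(self) -> float:
        return self._mean("bound_fraction")

    @property
    def mean_peak_D_moving(self) -> float | None:
        return self._mean("peak_D_moving")

    @property
    def mean_mean_D_moving(self) -> float | None:
        return self._mean("mean_D_moving")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.to_dict() for s in self.replicates])


def aggregate_replicates(summaries: list[DynamicsSummary]) -> ReplicateSummary:
    """Bundle replicate summaries of one condition; means are arithmetic."""
    if not summaries:
        raise ValueError("no summaries given")
    conditions = {s.condition for s in summaries}
    if len(conditions) != 1:
        raise ValueError(f"mixed condition labels: {sorted(conditions)}")
    return ReplicateSummary(condition=summaries[0].condition, replicates=list(summaries))


def compare_conditions(groups: list[ReplicateSummary]) -> dict[str, pd.DataFrame]:
    """Long-format statistic table plus pairwise differences of means.

    Returns ``{"values": ..., "differences": ...}``; differences are
    (condition A mean) − (condition B mean) for every ordered pair A ≠ B.
    """
    if len(groups) < 2:
        raise ValueError("need at least two conditions to compare")
    stats = ["bound_fraction", "peak_D_moving", "mean_D_moving"]
    rows = []
    for g in groups:
        for s in g.replicates:
            for stat in stats:
                rows.append(
                    {
                        "condition": g.condition,
                        "replicate": s.replicate,
                        "statistic": stat,
                        "value": getattr(s, stat),
                    }
                )
    values = pd.DataFrame(rows)

    diff_rows = []
    means = {
        g.condition: {
            "bound_fraction": g.mean_bound_fraction,
            "peak_D_moving": g.mean_peak_D_moving,
            "mean_D_moving": g.mean_mean_D_moving,
        }
        for g in groups
    }
    names = [g.condition for g in groups]
    for a in names:
        for b in names:
            if a == b:
                continue
            for stat in stats:
                ma, mb = means[a][stat], means[b][stat]
                diff = None if ma is None or mb is None else ma - mb
                diff_rows.append(
                    {"condition_a": a, "condition_b": b, "statistic": stat, "difference": diff}
                )
    return {"values": values, "differences": pd.DataFrame(diff_rows)}
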