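"""Configuration objects for acquisition, tracking, inference and full runs.

Defaults follow the acquisition and processing settings of fast
single-particle tracking (fSPT) of HaloTag-labeled transcription factors:
5.48 ms frames (~182 Hz), 0.16 µm pixels, a 0.7 µm detection slab, and the
detection/localization/linking parameterization used to build trajectories
from raw movies.  Every numeric default is a plain field so configurations
round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "AcquisitionConfig",
    "DetectConfig",
    "LocalizeConfig",
    "LinkConfig",
    "FrameFilterConfig",
    "TrackingConfig",
    "GridConfig",
    "InferenceConfig",
    "RunConfig",
    "load_config",
    "save_config",
]


@dataclass
class AcquisitionConfig:
    """Imaging geometry and timing.

    Parameters
    ----------
    frame_interval_s
        Camera frame interval in seconds.  The default, 0.00548 s,
        corresponds to ~182 Hz imaging.
    pixel_size_um
        Back-projected camera pixel size in µm.
    focal_depth_um
        Effective axial detection depth (``dz``) in µm: molecules are
        detectable while their axial position lies within ±dz/2 of focus.
    fov_px
        Field of view as (height, width) in pixels.
    n_frames
        Number of frames per movie.  Movies are acquired until the sample
        is fully photobleached, typically 800-1600 frames.
    """

    frame_interval_s: float = 0.00548
    pixel_size_um: float = 0.16
    focal_depth_um: float = 0.7
    fov_px: tuple[int, int] = (128, 128)
    n_frames: int = 800

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.focal_depth_um <= 0:
            raise ValueError("focal_depth_um must be positive")
        self.fov_px = (int(self.fov_px[0]), int(self.fov_px[1]))
        if min(self.fov_px) < 32:
            raise ValueError("fov_px dimensions must be >= 32")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")

    @property
    def frame_rate_hz(self) -> float:
        """Imaging rate in frames per second (1 / frame interval)."""
        return 1.0 / self.frame_interval_s

    @property
    def fov_um(self) -> tuple[float, float]:
        return (self.fov_px[0] * self.pixel_size_um, self.fov_px[1] * self.pixel_size_um)


@dataclass
class DetectConfig:
    """Spot detection via a generalized log-likelihood ratio (LLR) test.

    ``kernel_sigma_px`` (k) is the width of the Gaussian spot template,
    ``window_px`` (w) the side of the square test window, and ``threshold``
    (t) the LLR statistic cutoff.
    """

    kernel_sigma_px: float = 1.0
    window_px: int = 15
    threshold: float = 18.0

    def __post_init__(self) -> None:
        if self.window_px % 2 == 0:
            raise ValueError("window_px must be odd")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class LocalizeConfig:
    """Sub-pixel localization by integrated-Gaussian least squares."""

    window_px: int = 9
    psf_sigma_px: float = 1.0
    ridge: float = 0.001
    max_iter: int = 20
    damp: float = 0.3

    def __post_init__(self) -> None:
        if self.window_px % 2 == 0:
            raise ValueError("window_px must be odd")


@dataclass
class LinkConfig:
    """Frame-to-frame linking with a Euclidean cost and hard search radius.

    ``max_blinks = 0`` means no gap closing: a molecule that disappears for
    even one frame starts a new trajectory.  Frames with more than
    ``max_spots_per_frame`` detections are excluded from linking.
    ``min_intensity`` and ``scale`` are accepted for config compatibility;
    ``scale`` has no effect here and emits a warning when nonzero use is
    attempted via config loading.
    """

    search_radius_um: float = 1.0
    max_blinks: int = 0
    max_spots_per_frame: int = 7
    min_intensity: float = 0.0
    scale: float = 7.0

    def __post_init__(self) -> None:
        if self.search_radius_um <= 0:
            raise ValueError("search_radius_um must be positive")
        if self.max_blinks != 0:
            raise ValueError("only max_blinks = 0 (no gap closing) is supported")


@dataclass
class FrameFilterConfig:
    """Dense-frame filter: drop frames whose smoothed detection count is high.

    Per-frame detection counts are smoothed with a centered uniform kernel
    of ``smooth_kernel_frames`` frames (truncated at the sequence edges);
    frames are kept iff the smoothed count is strictly below
    ``max_smoothed_count``.
    """

    smooth_kernel_frames: int = 21
    max_smoothed_count: float = 7.0
    keep_strictly_below: bool = True

    def __post_init__(self) -> None:
        if self.smooth_kernel_frames < 1:
            raise ValueError("smooth_kernel_frames must be >= 1")


@dataclass
class TrackingConfig:
    """Full movie-to-trajectories parameterization."""

    detect: DetectConfig = field(default_factory=DetectConfig)
    localize: LocalizeConfig = field(default_factory=LocalizeConfig)
    link: LinkConfig = field(default_factory=LinkConfig)
    filter: FrameFilterConfig = field(default_factory=FrameFilterConfig)
    start_frame: int = 0


@dataclass
class GridConfig:
    """State-grid geometry for the likelihood and occupation inference."""

    d_min: float = 0.01
    d_max: float = 100.0
    n_diff_coefs: int = 101
    sigma_min: float = 0.0
    sigma_max: float = 0.08
    n_loc_errors: int = 17
    bound_threshold: float = 0.1


@dataclass
class InferenceConfig:
    """Variational occupation inference and defocalization correction."""

    prior_weight: float | None = None  # None -> one median-length trajectory
    max_iter: int = 1000
    tol: float = 1e-8
    defoc_correction: str = "slab_reflect"  # or "absorbing" or "none"
    bleach_prob_per_frame: float | None = None  # retention per frame = 1 - this


@dataclass
class RunConfig:
    """One pipeline run: acquisition + tracking + grid/inference + labels."""

    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    condition: str = "condition"
    replicate: str = "rep1"
    seed: int = 0


def _to_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _from_dict(cls: type, data: dict[str, Any]) -> Any:
    kwargs: dict[str, Any] = {}
    known = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in known:
            warnings.warn(f"{cls.__name__}: ignoring unknown config key {key!r}")
            continue
        f = known[key]
        ftype = f.default_factory() if f.default_factory is not dataclasses.MISSING else None
        if dataclasses.is_dataclass(ftype) and isinstance(value, dict):
            kwargs[key] = _from_dict(type(ftype), value)
        elif key == "fov_px" and isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def config_to_dict(config: Any) -> dict[str, Any]:
    """Serialize any config dataclass to a plain dictionary."""
    return _to_dict(config)


def save_config(config: Any, path: str) -> None:
    """Write a config dataclass to a YAML file."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(config), fh, sort_keys=False)


def load_config(path: str, cls: type = RunConfig) -> Any:
    """Read a YAML file into a config dataclass (``RunConfig`` by default)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(cls, data)
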