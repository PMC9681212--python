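"""Spot detection by a generalized log-likelihood ratio (LLR) test.

Each pixel is scored by testing "pixel-integrated Gaussian spot of width k
plus flat background" against "flat background only" under i.i.d. Gaussian
noise, over a w×w window centered on the pixel.  With r the normalized
correlation between the mean-subtracted window and the mean-subtracted
Gaussian template, the statistic is

    T = -(N/2) · ln(1 - r²),   N = w²,

which is monotone in the evidence for a spot.  Candidates are local maxima
of T exceeding the threshold t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import DetectConfig

__all__ = ["SpotDetection", "detect_spots", "llr_map"]


@dataclass
class SpotDetection:
    """One detected spot; positions in pixels (and µm once converted)."""

    frame: int
    y_px: float
    x_px: float
    intensity: float = 0.0
    converged: bool = False
    x_um: float | None = None
    y_um: float | None = None


def _gaussian_template(sigma: float, w: int) -> np.ndarray:
    half = w // 2
    g = np.arange(-half, half + 1)
    k1 = np.exp(-(g**2) / (2.0 * sigma**2))
    return np.outer(k1, k1)


def llr_map(image: np.ndarray, config: DetectConfig | None = None) -> np.ndarray:
    """Per-pixel LLR statistic for a Gaussian spot versus flat background."""
    config = config or DetectConfig()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("detection input must be a 2-D image")
    w = config.window_px
    if w > min(img.shape):
        raise ValueError("detection window does not fit inside the image")
    n = w * w

    g = _gaussian_template(config.kernel_sigma_px, w)
    g0 = g - g.mean()
    ss_g = float((g0**2).sum())

    # Windowed cross-products via uniform filtering.
    num = ndimage.correlate(img, g0, mode="reflect")
    local_mean = ndimage.uniform_filter(img, size=w, mode="reflect")
    local_mean_sq = ndimage.uniform_filter(img**2, size=w, mode="reflect")
    ss_img = n * np.maximum(local_mean_sq - local_mean**2, 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_img > 0, num**2 / (ss_g * ss_img), 0.0)
    r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
    return -(n / 2.0) * np.log1p(-r2)


def detect_spots(
    image: np.ndarray,
    config: DetectConfig | None = None,
    frame: int = 0,
    pixel_size_um: float | None = None,
) -> list[SpotDetection]:
    """Detect spots in one frame; returns integer-pixel candidates.

    A pixel is a detection if its LLR statistic exceeds the threshold and
    is the maximum within a window_px-sized neighborhood (one detection per
    local maximum).  Amplitude estimates (template regression coefficient)
    are attached as ``intensity``.
    """
    config = config or DetectConfig()
    T = llr_map(image, config)
    w = config.window_px
    local_max = T == ndimage.maximum_filter(T, size=w, mode="constant", cval=-np.inf)
    candidates = np.argwhere(local_max & (T > config.threshold))

    img = np.asarray(image, dtype=float)
    g = _gaussian_template(config.kernel_sigma_px, w)
    g0 = g - g.mean()
    ss_g = float((g0**2).sum())
    amp_map = ndimage.correlate(img, g0, mode="reflect") / ss_g

    out = []
    for y, x in candidates:
        det = SpotDetection(
            frame=frame,
            y_px=float(y),
            x_px=float(x),
            intensity=float(max(amp_map[y, x], 0.0)),
        )
        if pixel_size_um is not None:
            det.x_um = det.x_px * pixel_size_um
            det.y_um = det.y_px * pixel_size_um
        out.append(det)
    return out
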