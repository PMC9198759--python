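"""Background-calibrated quantitative tau burden on 8-bit grayscale sections.

DAB-immunostained tau (tangles, threads, pretangles) is darker than unstained
tissue.  On each digitized slide the white matter serves as the stain-free
reference: its per-pixel gray-value mean and standard deviation define an
image-specific threshold

    threshold = mean_gray - k * sd_gray        (k = 0.75 by default)

and every region pixel strictly below the threshold counts as tau-positive.
The burden readout per region is the tau ratio

    tau_ratio = n_positive / n_negative

which is scale-invariant, so no physical pixel size is assumed.  No color
deconvolution is performed: quantification operates on the 8-bit grayscale
conversion directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BackgroundStats",
    "ThresholdParams",
    "TauQuantResult",
    "white_matter_stats",
    "compute_threshold",
    "quantify_region",
    "quantify_slide",
    "MeasurementError",
]

DEFAULT_K = 0.75


class MeasurementError(ValueError):
    """Raised when a mask is empty after exclusions or an image is malformed."""


@dataclass(frozen=True)
class BackgroundStats:
    """White-matter gray-value statistics (population-SD divisor)."""

    mean_gray: float
    sd_gray: float
    n_pixels: int

    def __post_init__(self):
        if not (0.0 <= self.mean_gray <= 255.0):
            raise MeasurementError(f"mean_gray out of 8-bit range: {self.mean_gray}")
        if self.sd_gray < 0 or self.n_pixels <= 0:
            raise MeasurementError("sd_gray must be >= 0 and n_pixels > 0")


@dataclass(frozen=True)
class ThresholdParams:
    k: float = DEFAULT_K

    def __post_init__(self):
        if self.k <= 0:
            raise MeasurementError(f"threshold multiplier k must be > 0, got {self.k}")


@dataclass(frozen=True)
class TauQuantResult:
    n_positive: int
    n_negative: int
    tau_ratio: float  # math.inf when saturated
    threshold_used: float
    region_id: str = ""
    saturated: bool = False


def _as_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2:
        raise MeasurementError(f"expected a single-channel 2-D image, got shape {img.shape}")
    return img


def _effective_mask(mask: np.ndarray, exclusion_mask: np.ndarray | None, shape) -> np.ndarray:
    m = np.asarray(mask, dtype=bool)
    if m.shape != shape:
        raise MeasurementError(f"mask shape {m.shape} != image shape {shape}")
    if exclusion_mask is not None:
        ex = np.asarray(exclusion_mask, dtype=bool)
        if ex.shape != shape:
            raise MeasurementError(f"exclusion mask shape {ex.shape} != image shape {shape}")
        m = m & ~ex
    return m


def white_matter_stats(
    image: np.ndarray,
    wm_mask: np.ndarray,
    exclusion_mask: np.ndarray | None = None,
) -> BackgroundStats:
    """Mean/SD of white-matter pixel gray values, after manual exclusions.

    Pixels under ``exclusion_mask`` (holes, tears, overlaps, background) are
    dropped before computing statistics.  The SD uses the population (n)
    divisor, consistent with all cohort summaries in this package.
    """
    img = _as_gray(image)
    m = _effective_mask(wm_mask, exclusion_mask, img.shape)
    n = int(m.sum())
    if n == 0:
        raise MeasurementError("white-matter mask is empty after exclusions")
    vals = img[m].astype(np.float64)
    return BackgroundStats(float(vals.mean()), float(vals.std(ddof=0)), n)


def compute_threshold(
    stats: BackgroundStats, params: ThresholdParams = ThresholdParams()
) -> float:
    """Image-specific positivity threshold: ``mean_gray - k * sd_gray``.

    The value is returned unclamped and may be fractional; with a degenerate
    (constant) background it equals the background mean.
    """
    return stats.mean_gray - params.k * stats.sd_gray


def quantify_region(
    image: np.ndarray,
    region_mask: np.ndarray,
    exclusion_mask: np.ndarray | None,
    threshold: float,
    region_id: str = "",
) -> TauQuantResult:
    """Count tau-positive (gray strictly below threshold) vs negative pixels.

    Pixels exactly at the threshold count as negative.  A region with zero
    negative pixels yields a flagged, infinite ratio rather than an error so
    batch runs stay total; downstream statistics drop flagged values.
    """
    img = _as_gray(image)
    m = _effective_mask(region_mask, exclusion_mask, img.shape)
    n_total = int(m.sum())
    if n_total == 0:
        raise MeasurementError(f"region {region_id!r} is empty after exclusions")
    vals = img[m]
    n_pos = int((vals < threshold).sum())
    n_neg = n_total - n_pos
    if n_neg == 0:
        return TauQuantResult(n_pos, 0, math.inf, threshold, region_id, saturated=True)
    return TauQuantResult(n_pos, n_neg, n_pos / n_neg, threshold, region_id)


def quantify_slide(
    image: np.ndarray,
    wm_mask: np.ndarray,
    region_masks: dict[str, np.ndarray],
    exclusion_mask: np.ndarray | None = None,
    params: ThresholdParams = ThresholdParams(),
) -> dict[str, TauQuantResult]:
    """Full per-slide protocol: background stats, threshold, then every region."""
    stats = white_matter_stats(image, wm_mask, exclusion_mask)
    thr = compute_threshold(stats, params)
    return {
        rid: quantify_region(image, mask, exclusion_mask, thr, rid)
        for rid, mask in region_masks.items()
    }
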