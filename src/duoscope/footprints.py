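"""Intensity-based cell detection for the static channel.

The static channel carries no activity dynamics, so cells are found from a
summary image alone: local maxima of the smoothed image above an intensity
threshold, followed by growth of a round above-half-max region around each
peak. Elongated or out-of-size features are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label, perimeter as cc_perimeter

from .core import DegenerateDataError, Footprint, GeometryError

__all__ = ["DetectionParams", "detect_local_maxima", "grow_round_footprint", "detect_cells"]


@dataclass(frozen=True)
class DetectionParams:
    """Knobs of the static-channel detection pipeline.

    ``intensity_threshold`` is interpreted as a quantile of the smoothed
    summary image when ``threshold_is_quantile`` (default), otherwise as an
    absolute intensity.
    """

    smoothing_sigma: float = 1.5
    min_distance: int = 7
    intensity_threshold: float = 0.95
    threshold_is_quantile: bool = True
    radius_bounds: tuple[float, float] = (2.0, 8.0)
    roundness_min: float = 0.7

    def __post_init__(self) -> None:
        if self.min_distance < 1:
            raise ValueError("min_distance must be >= 1")
        lo, hi = self.radius_bounds
        if not lo < hi:
            raise ValueError("radius_bounds must satisfy min < max")
        if not 0.0 <= self.roundness_min <= 1.0:
            raise ValueError("roundness_min must be in [0, 1]")
        if self.threshold_is_quantile and not 0.0 <= self.intensity_threshold <= 1.0:
            raise ValueError("quantile threshold must be in [0, 1]")


def _smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise GeometryError("expected a 2D image")
    if not np.all(np.isfinite(image)):
        raise DegenerateDataError("image must be finite-valued")
    return ndimage.gaussian_filter(image, sigma) if sigma > 0 else image


def _threshold(raw: np.ndarray, params: DetectionParams) -> float:
    # quantile taken on the raw image: smoothing shrinks pure noise ~5x while
    # leaving blob cores nearly intact, so this rejects noise-only peaks
    if params.threshold_is_quantile:
        return float(np.quantile(raw, params.intensity_threshold))
    return float(params.intensity_threshold)


def detect_local_maxima(image: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Peaks of the smoothed image: strictly above threshold, >= min_distance apart.

    Returns an (n, 2) integer array of (row, col) coordinates sorted by
    descending smoothed intensity; ties are broken by ascending (row, col).
    An image with no qualifying peak yields an empty array.
    """
    image = np.asarray(image, dtype=float)
    smoothed = _smooth(image, params.smoothing_sigma)
    thr = _threshold(image, params)
    peaks = peak_local_max(
        smoothed,
        min_distance=params.min_distance,
        threshold_abs=thr,
        exclude_border=False,
    )
    if peaks.size == 0:
        return peaks.reshape(0, 2)
    vals = smoothed[peaks[:, 0], peaks[:, 1]]
    keep = vals > thr  # strict: a flat image has no peaks
    peaks, vals = peaks[keep], vals[keep]
    order = np.lexsort((peaks[:, 1], peaks[:, 0], -vals))
    return peaks[order]


def grow_round_footprint(
    image: np.ndarray, peak: tuple[int, int], params: DetectionParams
) -> Footprint | None:
    """Grow the above-half-max region around ``peak``; reject non-round features.

    Background is the median of an annulus just outside the maximum allowed
    radius. The footprint weights are background-subtracted raw intensities
    inside the accepted region. Returns ``None`` on rejection (roundness
    below ``roundness_min`` or equivalent radius outside ``radius_bounds``).
    """
    image = np.asarray(image, dtype=float)
    smoothed = _smooth(image, params.smoothing_sigma)
    h, w = image.shape
    r0, c0 = int(peak[0]), int(peak[1])
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise GeometryError("peak outside image")

    r_max = params.radius_bounds[1]
    win = int(np.ceil(2.0 * r_max)) + 2
    rlo, rhi = max(0, r0 - win), min(h, r0 + win + 1)
    clo, chi = max(0, c0 - win), min(w, c0 + win + 1)
    sub = smoothed[rlo:rhi, clo:chi]
    pr, pc = r0 - rlo, c0 - clo

    neighborhood = sub[max(0, pr - 1):pr + 2, max(0, pc - 1):pc + 2]
    if sub[pr, pc] + 1e-12 < neighborhood.max():
        raise ValueError("peak is not a local maximum of the smoothed image")

    # low-percentile window background: robust to neighbours, and unlike an
    # annulus median it does not adapt away oversized blobs
    background = float(np.percentile(sub, 10.0))
    peak_val = float(sub[pr, pc])
    if peak_val <= background:
        return None

    half = background + 0.5 * (peak_val - background)
    mask = sub >= half
    labels = cc_label(mask, connectivity=2)
    region = labels == labels[pr, pc]

    area = int(region.sum())
    radius = float(np.sqrt(area / np.pi))
    if not params.radius_bounds[0] <= radius <= params.radius_bounds[1]:
        return None
    perim = cc_perimeter(region, neighborhood=4)
    roundness = min(1.0, 4.0 * np.pi * area / perim**2) if perim > 0 else 1.0
    if roundness < params.roundness_min:
        return None

    weights = np.zeros_like(image)
    raw_sub = image[rlo:rhi, clo:chi]
    weights[rlo:rhi, clo:chi][region] = np.clip(raw_sub[region] - background, 0.0, None)
    if weights.sum() <= 0:
        return None
    return Footprint(cell_id=-1, weights=weights)


def detect_cells(movie_or_summary: np.ndarray, params: DetectionParams) -> list[Footprint]:
    """Detect round cells in a summary image (or mean projection of a stack).

    Cell ids are assigned in detection order (descending peak intensity).
    """
    arr = np.asarray(movie_or_summary, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=0)
    peaks = detect_local_maxima(arr, params)
    footprints: list[Footprint] = []
    for pk in peaks:
        fp = grow_round_footprint(arr, (int(pk[0]), int(pk[1])), params)
        if fp is not None:
            fp.cell_id = len(footprints)
            footprints.append(fp)
    return footprints
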