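"""Per-section detection of labeled projection signal.

Each coronal section is processed independently:

1. a smooth background field ``B`` is estimated by clipping the section at a
   robust scalar baseline (``min(I, B0)``, with ``B0`` the section median)
   and then running ten passes of a 9x9 uniform-mean filter;
2. the section is background subtracted, ``max(I - B, 0)``;
3. smoothed with a 5x5 truncated, renormalized Gaussian;
4. thresholded at a per-pixel level ``max(m * B, t)`` where ``t`` is the
   Yen maximum-correlation threshold of the smoothed section, clipped into a
   configured range, and ``m`` (default 4) guards against residual
   background.

The clipping by ``min(I, B0)`` makes the background estimate insensitive to
sparse bright signal, so axon tracts do not inflate their own threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DataError, GeometryError, InputError
from .io_atlas import BinaryMask, Volume3D


@dataclass
class DetectionParams:
    """Tunables of the per-section detection pipeline.

    ``yen_clip_min``/``yen_clip_max`` bound the Yen threshold; ``None`` means
    the per-section defaults (95th percentile of the smoothed section, and
    unbounded above).
    """

    background_iterations: int = 10
    background_kernel: int = 9
    gaussian_kernel: int = 5
    gaussian_sigma: float = 1.0
    background_multiplier: float = 4.0
    yen_clip_min: Optional[float] = None
    yen_clip_max: Optional[float] = None
    yen_bins: int = 256

    def __post_init__(self) -> None:
        for k in (self.background_kernel, self.gaussian_kernel):
            if k < 3 or k % 2 == 0:
                raise InputError(f"kernel sizes must be odd and >= 3, got {k}")
        if self.background_multiplier <= 0:
            raise InputError("background multiplier must be positive")
        if (
            self.yen_clip_min is not None
            and self.yen_clip_max is not None
            and self.yen_clip_min > self.yen_clip_max
        ):
            raise InputError("yen_clip_min must not exceed yen_clip_max")


@dataclass
class SectionDetectionResult:
    background: np.ndarray
    filtered: np.ndarray
    yen_threshold_raw: float
    yen_threshold_clipped: float
    degenerate: bool
    mask: np.ndarray


def estimate_background(
    section: np.ndarray, params: DetectionParams = DetectionParams()
) -> np.ndarray:
    """Estimate the smooth background field of one section.

    ``B0`` is the section median; the section is clipped at ``B0`` from above
    (so bright signal cannot leak into the estimate) and the clipped image is
    mean-filtered ``background_iterations`` times with a
    ``background_kernel``-sized uniform template, reflecting at borders.
    """
    section = np.asarray(section, dtype=np.float64)
    if section.size == 0 or np.all(np.isnan(section)):
        raise DataError("empty or all-NaN section")
    b0 = float(np.nanmedian(section))
    b = np.minimum(section, b0)
    for _ in range(params.background_iterations):
        b = ndimage.uniform_filter(b, size=params.background_kernel, mode="reflect")
    return b


def subtract_background(section: np.ndarray, background: np.ndarray) -> np.ndarray:
    """``max(I - B, 0)`` elementwise."""
    section = np.asarray(section, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    if section.shape != background.shape:
        raise GeometryError(
            f"shape mismatch {section.shape} vs {background.shape}"
        )
    return np.maximum(section - background, 0.0)


def gaussian_kernel_2d(size: int, sigma: float) -> np.ndarray:
    """Truncated, renormalized 2D Gaussian kernel of odd ``size``."""
    half = size // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-(x**2) / (2.0 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


def gaussian_filter(
    section: np.ndarray, params: DetectionParams = DetectionParams()
) -> np.ndarray:
    """Convolve with the truncated Gaussian kernel, reflecting at borders."""
    k = gaussian_kernel_2d(params.gaussian_kernel, params.gaussian_sigma)
    return ndimage.convolve(
        np.asarray(section, dtype=np.float64), k, mode="reflect"
    )


def yen_threshold(
    hist: np.ndarray,
    bin_centers: np.ndarray,
    params: DetectionParams = DetectionParams(),
) -> Tuple[float, float, bool]:
    """Yen's maximum-correlation threshold on a histogram.

    Returns ``(raw, clipped, degenerate)``.  The raw threshold is the bin
    center maximizing Yen's criterion

        TC(t) = -ln(S1(t) * S2(t)) + 2 * ln(P1(t) * P2(t)),

    with ``P`` the cumulative class probabilities and ``S`` the cumulative
    sums of squared probabilities; ties break toward the lower gray level.
    The clipped value is the raw one bounded into
    ``[yen_clip_min, yen_clip_max]``.  A single-populated-bin histogram is
    degenerate: its level is returned unchanged.
    """
    hist = np.asarray(hist, dtype=np.float64)
    bin_centers = np.asarray(bin_centers, dtype=np.float64)
    if hist.sum() <= 0:
        raise DataError("histogram is empty")
    nonzero = np.flatnonzero(hist)
    lo = params.yen_clip_min if params.yen_clip_min is not None else -np.inf
    hi = params.yen_clip_max if params.yen_clip_max is not None else np.inf
    if len(nonzero) < 2:
        raw = float(bin_centers[nonzero[0]])
        return raw, float(min(max(raw, lo), hi)), True
    p = hist / hist.sum()
    pp = p * p
    p1 = np.cumsum(p)
    s1 = np.cumsum(pp)
    # tail sums by reversed cumsum: a plain s1[-1] - s1 cancels catastrophically
    # when the upper class is tiny and can flip the criterion to +inf
    p2 = np.concatenate([np.cumsum(p[::-1])[::-1][1:], [0.0]])
    s2 = np.concatenate([np.cumsum(pp[::-1])[::-1][1:], [0.0]])
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = -np.log(s1 * s2) + 2.0 * np.log(p1 * p2)
    valid = (p1 > 0) & (p2 > 0) & (s1 > 0) & (s2 > 0)
    crit = np.where(valid, crit, -np.inf)
    raw = float(bin_centers[int(np.argmax(crit))])
    return raw, float(min(max(raw, lo), hi)), False


def section_histogram(
    section: np.ndarray, params: DetectionParams = DetectionParams()
) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram for Yen thresholding.

    Integer sections use their native levels; float sections use
    ``yen_bins`` equal-width bins between min and max.
    """
    section = np.asarray(section)
    if np.issubdtype(section.dtype, np.integer):
        lo, hi = int(section.min()), int(section.max())
        levels = np.arange(lo, hi + 1)
        hist = np.bincount((section - lo).ravel(), minlength=len(levels))
        return hist.astype(np.float64), levels.astype(np.float64)
    lo, hi = float(section.min()), float(section.max())
    if hi == lo:
        return np.array([float(section.size)]), np.array([lo])
    hist, edges = np.histogram(section, bins=params.yen_bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return hist.astype(np.float64), centers


def binarize(
    filtered: np.ndarray,
    background: np.ndarray,
    clipped_threshold: float,
    params: DetectionParams = DetectionParams(),
) -> np.ndarray:
    """Foreground where the smoothed section exceeds ``max(m * B, t)``.

    A pixel must beat both the global clipped Yen threshold and
    ``background_multiplier`` times its local background estimate.
    """
    filtered = np.asarray(filtered, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    if filtered.shape != background.shape:
        raise GeometryError(
            f"shape mismatch {filtered.shape} vs {background.shape}"
        )
    per_pixel = np.maximum(
        params.background_multiplier * background, clipped_threshold
    )
    return filtered > per_pixel


def detect_section(
    section: np.ndarray, params: DetectionParams = DetectionParams()
) -> SectionDetectionResult:
    """Run the full per-section pipeline on one coronal section."""
    b = estimate_background(section, params)
    sub = subtract_background(section, b)
    filt = gaussian_filter(sub, params)
    p = params
    if p.yen_clip_min is None:
        p = DetectionParams(
            background_iterations=params.background_iterations,
            background_kernel=params.background_kernel,
            gaussian_kernel=params.gaussian_kernel,
            gaussian_sigma=params.gaussian_sigma,
            background_multiplier=params.background_multiplier,
            yen_clip_min=float(np.percentile(filt, 95)),
            yen_clip_max=params.yen_clip_max,
            yen_bins=params.yen_bins,
        )
    hist, centers = section_histogram(filt, p)
    raw, clipped, degen = yen_threshold(hist, centers, p)
    if degen:
        mask = np.zeros(section.shape, dtype=bool)
    else:
        mask = binarize(filt, b, clipped, p)
    return SectionDetectionResult(b, filt, raw, clipped, degen, mask)


def detect_volume(
    volume: Volume3D,
    params: DetectionParams = DetectionParams(),
    log_path: Optional[Union[str, Path]] = None,
) -> BinaryMask:
    """Apply the section pipeline to every coronal slice and stack the masks.

    When ``log_path`` is given, per-section thresholds are written as CSV
    (slice index, raw, clipped, degenerate).
    """
    masks = np.zeros(volume.shape, dtype=bool)
    rows = []
    for i in range(volume.shape[0]):
        res = detect_section(volume.data[i], params)
        masks[i] = res.mask
        rows.append(
            {
                "slice": i,
                "yen_raw": res.yen_threshold_raw,
                "yen_clipped": res.yen_threshold_clipped,
                "degenerate": res.degenerate,
            }
        )
    if log_path is not None:
        pd.DataFrame(rows).to_csv(log_path, index=False)
    return BinaryMask(masks, volume.voxel_size_um, volume.origin_um)
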