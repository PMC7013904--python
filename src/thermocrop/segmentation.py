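"""Canopy segmentation on the thermal grid.

The canopy is located in the visible overlap crop with the green-red
vegetation index GRVI = (G - R) / (G + R), positive for green vegetation.
Thresholding at GRVI >= 0.04 (inclusive) gives a binary mask, which is then
refined by a morphological closing (dilation followed by erosion with one
4x4 square structuring element) to fill interpolation holes, and cleaned by
removing connected components smaller than one tenth of the mask's
foreground area. The final mask selects the thermal pixels averaged into
the canopy temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .errors import NoCanopyError
from .radiometry import TemperatureMap
from .registration import OverlapView

__all__ = [
    "GrviMap",
    "CanopyMask",
    "SegmentationParams",
    "grvi",
    "threshold_mask",
    "morphological_refine",
    "remove_small_regions",
    "mean_masked_temperature",
]


@dataclass
class GrviMap:
    """Per-pixel green-red vegetation index in [-1, 1]; pixels with
    R + G = 0 carry the sentinel value 0."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1) or np.any(self.values > 1):
            raise ValueError("GRVI values must lie in [-1, 1]")


@dataclass
class CanopyMask:
    """Binary canopy mask on the thermal grid (1 = canopy)."""

    M: np.ndarray

    def __post_init__(self):
        M = np.asarray(self.M)
        if not np.isin(M, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.M = M.astype(np.uint8)

    @property
    def area(self) -> int:
        return int(self.M.sum())


@dataclass(frozen=True)
class SegmentationParams:
    """Threshold/refinement parameters; defaults are the values validated
    for a pre-senescence potato canopy."""

    grvi_threshold: float = 0.04
    kernel_size: int = 4
    min_region_fraction: float = 0.1

    def __post_init__(self):
        if not -1 < self.grvi_threshold < 1:
            raise ValueError(f"grvi_threshold must be in (-1, 1), got {self.grvi_threshold}")
        if self.kernel_size < 1:
            raise ValueError(f"kernel_size must be >= 1, got {self.kernel_size}")
        if not 0 <= self.min_region_fraction < 1:
            raise ValueError(
                f"min_region_fraction must be in [0, 1), got {self.min_region_fraction}"
            )


def grvi(rgb_star) -> GrviMap:
    """Compute (G - R)/(G + R) per pixel; blue is ignored.

    Zero-denominator (black) pixels are assigned 0 — they are never leaves
    and 0 falls below the canopy threshold.
    """
    pixels = rgb_star.rgb_star if isinstance(rgb_star, OverlapView) else np.asarray(rgb_star)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {pixels.shape}")
    r = pixels[:, :, 0].astype(float)
    g = pixels[:, :, 1].astype(float)
    denom = g + r
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(denom > 0, (g - r) / np.where(denom > 0, denom, 1.0), 0.0)
    return GrviMap(values)


def threshold_mask(grvi_map: GrviMap, tau: float = 0.04) -> CanopyMask:
    """Binary mask: 1 where GRVI >= tau (inclusive comparison)."""
    return CanopyMask((grvi_map.values >= tau).astype(np.uint8))


def _shift_accumulate(mask: np.ndarray, k: int, anchor: int, mode: str) -> np.ndarray:
    """Dilation (mode='or') / erosion (mode='and') by a k x k all-ones
    element anchored at (anchor, anchor), with constant-0 padding."""
    h, w = mask.shape
    padded = np.zeros((h + 2 * k, w + 2 * k), dtype=bool)
    padded[k : k + h, k : k + w] = mask.astype(bool)
    out = np.zeros((h, w), dtype=bool) if mode == "or" else np.ones((h, w), dtype=bool)
    for i in range(k):
        for j in range(k):
            dy, dx = i - anchor, j - anchor
            if mode == "or":
                # dilation: out(q) = OR over element offsets of in(q - offset)
                window = padded[k - dy : k - dy + h, k - dx : k - dx + w]
                out |= window
            else:
                # erosion: out(q) = AND over element offsets of in(q + offset)
                window = padded[k + dy : k + dy + h, k + dx : k + dx + w]
                out &= window
    return out


def morphological_refine(mask: CanopyMask, kernel_size: int = 4) -> CanopyMask:
    """Morphological closing with a square all-ones structuring element.

    The anchor of an even-sized element is fixed at the upper-left pixel of
    its central 2x2 block (index (k-1)//2); both passes pad with background,
    so structures touching the frame border may be slightly eroded.
    """
    h, w = mask.M.shape
    if kernel_size > min(h, w):
        raise ValueError(f"kernel size {kernel_size} exceeds mask extent {w}x{h}")
    anchor = (kernel_size - 1) // 2
    dilated = _shift_accumulate(mask.M, kernel_size, anchor, "or")
    eroded = _shift_accumulate(dilated, kernel_size, anchor, "and")
    return CanopyMask(eroded.astype(np.uint8))


def remove_small_regions(mask: CanopyMask, min_region_fraction: float = 0.1) -> CanopyMask:
    """Delete 8-connected components smaller than a fraction of the input's
    total foreground area (single pass: the area budget is computed once,
    before any deletion)."""
    total = mask.area
    if total == 0:
        return CanopyMask(mask.M.copy())
    labels = measure.label(mask.M, connectivity=2)
    threshold = min_region_fraction * total
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for region in measure.regionprops(labels):
        keep[region.label] = region.area >= threshold
    return CanopyMask(keep[labels].astype(np.uint8))


def mean_masked_temperature(T_map: TemperatureMap, mask: CanopyMask) -> tuple[float, int]:
    """Arithmetic mean of the temperature map over mask==1 pixels.

    Returns ``(T_canopy_K, n_pixels)``; an empty mask raises
    :class:`NoCanopyError` rather than producing 0/0.
    """
    if T_map.shape != mask.M.shape:
        raise ValueError(f"shape mismatch: map {T_map.shape} vs mask {mask.M.shape}")
    sel = mask.M.astype(bool)
    n = int(sel.sum())
    if n == 0:
        raise NoCanopyError("no canopy detected: refined mask is empty")
    return float(T_map.T_object[sel].mean()), n
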