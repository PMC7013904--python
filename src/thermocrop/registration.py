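"""Geometric alignment of the visible and thermal pixel grids.

The two sensors share one housing, so their grids are related by a fixed
axis-aligned scale plus an integer shift: scaling the visible frame by
(Sx, Sy) and placing the 320x240 thermal window at displacement (bx, by)
inside the scaled frame aligns pixel (x, y) of the thermal grid with pixel
(bx + x, by + y) of the scaled visible grid. The thermal counts are never
resampled — only the visible image, which merely localizes the canopy, is
interpolated.

Calibration uses manually selected control-point pairs from multiple
image pairs; each pair contributes an ordinary least-squares fit per axis
of ``x_irt = Sx * u_rgb - bx`` (and likewise for y), and the reported
parameters are the across-pair means with relative standard deviations
as percent uncertainties.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import SingularFitError, WindowOutOfBoundsError
from .radiometry import IRT_HEIGHT, IRT_WIDTH

__all__ = [
    "VisibleFrame",
    "RegistrationParams",
    "ControlPointSet",
    "OverlapView",
    "DEFAULT_REGISTRATION",
    "RGB_WIDTH",
    "RGB_HEIGHT",
    "estimate_registration",
    "scale_visible",
    "extract_overlap",
]

#: Native resolution of the supported visible sensor.
RGB_WIDTH = 2048
RGB_HEIGHT = 1536


def round_half_away(x) -> int:
    """Round half away from zero (0.5 -> 1, -0.5 -> -1)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass
class VisibleFrame:
    """An 8-bit RGB frame (channel order red, green, blue)."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"visible frame must be HxWx3, got shape {self.pixels.shape}")
        self.pixels = self.pixels.astype(np.uint8)
        if (self.width, self.height) != (RGB_WIDTH, RGB_HEIGHT):
            warnings.warn(
                f"visible frame is {self.width}x{self.height}; the supported sensor is "
                f"{RGB_WIDTH}x{RGB_HEIGHT}",
                stacklevel=2,
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class RegistrationParams:
    """Scale factors for the visible frame and the thermal window origin
    (bx, by) in scaled-visible pixel coordinates."""

    Sx: float
    Sy: float
    bx: int
    by: int
    rel_uncertainty_scale_pct: float = 0.0
    rel_uncertainty_shift_pct: float = 0.0
    n_pairs: int = 1

    def __post_init__(self):
        if not (0 < self.Sx < 1 and 0 < self.Sy < 1):
            raise ValueError(f"scale factors must lie in (0, 1), got ({self.Sx}, {self.Sy})")
        if self.bx < 0 or self.by < 0:
            raise ValueError(f"window origin must be non-negative, got ({self.bx}, {self.by})")


#: Calibrated defaults for the supported sensor pair.
DEFAULT_REGISTRATION = RegistrationParams(
    Sx=0.367, Sy=0.375, bx=219, by=189,
    rel_uncertainty_scale_pct=5.40, rel_uncertainty_shift_pct=2.33, n_pairs=50,
)


@dataclass
class ControlPointSet:
    """Manually selected correspondences between visible and thermal pixels.

    Stored as a table with columns ``pair_id, u_rgb, v_rgb, x_irt, y_irt``
    (0-based pixel coordinates, origin top-left).
    """

    points: pd.DataFrame

    REQUIRED_COLUMNS = ("pair_id", "u_rgb", "v_rgb", "x_irt", "y_irt")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.points.columns]
        if missing:
            raise ValueError(f"control-point table missing columns: {missing}")

    def groups(self):
        return self.points.groupby("pair_id", sort=True)

    @property
    def n_pairs(self) -> int:
        return self.points["pair_id"].nunique()


@dataclass
class OverlapView:
    """The 320x240x3 crop of the scaled visible frame that overlaps the
    thermal grid; pixel (x, y) corresponds to thermal pixel (x, y)."""

    rgb_star: np.ndarray
    origin: tuple[int, int]

    def __post_init__(self):
        self.rgb_star = np.asarray(self.rgb_star, dtype=np.uint8)
        if self.rgb_star.shape != (IRT_HEIGHT, IRT_WIDTH, 3):
            raise ValueError(
                f"overlap view must be {IRT_HEIGHT}x{IRT_WIDTH}x3, got {self.rgb_star.shape}"
            )


def _fit_axis(coord_rgb: np.ndarray, coord_irt: np.ndarray, axis_name: str, pair_id) -> tuple[float, float]:
    """OLS fit of ``irt = S * rgb - b`` for one axis; returns (S, b)."""
    if np.ptp(coord_rgb) == 0:
        raise SingularFitError(
            f"pair {pair_id!r}: all control points share one {axis_name}-coordinate; "
            "scale along that axis is unidentifiable"
        )
    slope, intercept = np.polyfit(coord_rgb, coord_irt, 1)
    return float(slope), float(-intercept)


def estimate_registration(points: ControlPointSet) -> RegistrationParams:
    """Estimate (Sx, Sy, bx, by) from control points.

    Each image pair is fitted independently per axis by ordinary least
    squares; the result averages across pairs and reports relative standard
    deviations (percent of the mean, averaged over the two axes) for the
    scale and shift. The window origin is rounded half away from zero to
    integers.
    """
    sx, sy, bx, by = [], [], [], []
    for pair_id, grp in points.groups():
        if len(grp) < 2:
            raise SingularFitError(f"pair {pair_id!r} has {len(grp)} control point(s); >=2 required")
        s, b = _fit_axis(grp["u_rgb"].to_numpy(float), grp["x_irt"].to_numpy(float), "u", pair_id)
        sx.append(s)
        bx.append(b)
        s, b = _fit_axis(grp["v_rgb"].to_numpy(float), grp["y_irt"].to_numpy(float), "v", pair_id)
        sy.append(s)
        by.append(b)
    n = len(sx)

    def rel_pct(values_x, values_y):
        if n < 2:
            return 0.0
        rx = np.std(values_x, ddof=1) / abs(np.mean(values_x))
        ry = np.std(values_y, ddof=1) / abs(np.mean(values_y))
        return float(100.0 * (rx + ry) / 2.0)

    return RegistrationParams(
        Sx=float(np.mean(sx)),
        Sy=float(np.mean(sy)),
        bx=round_half_away(float(np.mean(bx))),
        by=round_half_away(float(np.mean(by))),
        rel_uncertainty_scale_pct=rel_pct(sx, sy),
        rel_uncertainty_shift_pct=rel_pct(bx, by),
        n_pairs=n,
    )


def scale_visible(frame: VisibleFrame, Sx: float, Sy: float) -> VisibleFrame:
    """Bilinearly resample the visible frame to (round(W*Sx), round(H*Sy)).

    Output pixel centre (X, Y) samples input coordinates
    ``u = (X + 0.5) * W/W_out - 0.5`` (edge-clamped), the standard
    area-consistent resize mapping. Thermal data is never touched here.
    """
    if Sx <= 0 or Sy <= 0:
        raise ValueError(f"scale factors must be positive, got ({Sx}, {Sy})")
    if Sx == 1.0 and Sy == 1.0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return VisibleFrame(frame.pixels.copy())
    h, w = frame.height, frame.width
    out_w = round_half_away(w * Sx)
    out_h = round_half_away(h * Sy)
    uu = (np.arange(out_w) + 0.5) * (w / out_w) - 0.5
    vv = (np.arange(out_h) + 0.5) * (h / out_h) - 0.5
    vg, ug = np.meshgrid(vv, uu, indexing="ij")
    coords = np.stack([vg, ug])
    out = np.empty((out_h, out_w, 3), dtype=np.uint8)
    for c in range(3):
        chan = ndimage.map_coordinates(
            frame.pixels[:, :, c].astype(float), coords, order=1, mode="nearest"
        )
        out[:, :, c] = np.clip(np.rint(chan), 0, 255).astype(np.uint8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return VisibleFrame(out)


def extract_overlap(scaled: VisibleFrame, params: RegistrationParams) -> OverlapView:
    """Crop the 320x240 window at (bx, by) from the scaled visible frame."""
    bx, by = params.bx, params.by
    over_x = bx + IRT_WIDTH - scaled.width
    over_y = by + IRT_HEIGHT - scaled.height
    if bx < 0 or by < 0 or over_x > 0 or over_y > 0:
        raise WindowOutOfBoundsError(
            f"overlap window at ({bx}, {by}) overhangs the {scaled.width}x{scaled.height} "
            f"scaled frame by ({max(over_x, 0)}, {max(over_y, 0)}) px"
        )
    crop = scaled.pixels[by : by + IRT_HEIGHT, bx : bx + IRT_WIDTH, :]
    return OverlapView(rgb_star=crop.copy(), origin=(bx, by))
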