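"""Radiometric conversion of raw thermal counts to object temperature.

Uncooled thermal cameras report a raw 16-bit count ``S`` per pixel. The
count relates to scene temperature through a Planck-form calibration

    RAW(T) = R1 / (R2 * (exp(B / T) - F)) - O

with camera-specific constants ``R1, R2, B, F, O``. The sensor integrates
two radiance components: emission from the object (weighted by its
emissivity ``eps``) and ambient radiation reflected off the object
(weighted by ``1 - eps``). Removing the reflected component gives the
object-only count

    RAW_object = (S - (1 - eps) * RAW(T_reflected)) / eps

which inverts to the object temperature in kelvin

    T_object = B / ln(R1 / (R2 * (RAW_object + O)) + F).

All temperatures in this module are kelvin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import RadiometricDomainError, RoiError

__all__ = [
    "PlanckConstants",
    "RadiometricSettings",
    "ThermalFrame",
    "TemperatureMap",
    "Rect",
    "IRT_WIDTH",
    "IRT_HEIGHT",
    "DEFAULT_EMISSIVITY",
    "temperature_to_raw",
    "raw_to_temperature",
    "correct_reflection",
    "frame_to_temperature",
    "estimate_reflected_temperature",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
]

#: Native resolution of the supported thermal sensor.
IRT_WIDTH = 320
IRT_HEIGHT = 240

#: Standard leaf emissivity used throughout the pipeline.
DEFAULT_EMISSIVITY = 0.96

KELVIN_OFFSET = 273.15


def celsius_to_kelvin(t_c):
    return np.asarray(t_c, dtype=float) + KELVIN_OFFSET if np.ndim(t_c) else float(t_c) + KELVIN_OFFSET


def kelvin_to_celsius(t_k):
    return np.asarray(t_k, dtype=float) - KELVIN_OFFSET if np.ndim(t_k) else float(t_k) - KELVIN_OFFSET


class Rect(NamedTuple):
    """Axis-aligned rectangle in pixel coordinates (origin top-left).

    ``x``/``y`` index the left/top edge; the rectangle covers columns
    ``[x, x + width)`` and rows ``[y, y + height)``.
    """

    x: int
    y: int
    width: int
    height: int

    def validate_within(self, frame_width: int, frame_height: int) -> None:
        if self.width <= 0 or self.height <= 0:
            raise RoiError(f"ROI {self} is empty (non-positive extent)")
        if self.x < 0 or self.y < 0 or self.x + self.width > frame_width or self.y + self.height > frame_height:
            raise RoiError(
                f"ROI {self} exceeds frame bounds {frame_width}x{frame_height}"
            )

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y, self.y + self.height), slice(self.x, self.x + self.width)


@dataclass(frozen=True)
class PlanckConstants:
    """Per-camera Planck calibration constants.

    ``F`` defaults to 1 (the common published parameterization); ``O`` is a
    signed raw-count offset, typically negative.
    """

    R1: float
    R2: float
    B: float
    O: float
    F: float = 1.0

    def __post_init__(self):
        for name in ("R1", "R2", "B"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Planck constant {name} must be positive, got {getattr(self, name)}")


@dataclass(frozen=True)
class RadiometricSettings:
    """Per-acquisition emissivity and reflected ambient temperature (K)."""

    emissivity: float = DEFAULT_EMISSIVITY
    T_reflected_K: float = 293.15

    def __post_init__(self):
        if not 0.0 < self.emissivity <= 1.0:
            raise ValueError(f"emissivity must be in (0, 1], got {self.emissivity}")
        if self.T_reflected_K <= 0:
            raise ValueError(f"T_reflected_K must be positive, got {self.T_reflected_K}")


@dataclass
class ThermalFrame:
    """A raw thermal frame: unsigned 16-bit counts plus acquisition metadata.

    ``acquisition`` holds optional protocol metadata (timestamp, viewing
    angle in degrees, object distance in metres); it never affects the
    radiometric computation.
    """

    raw: np.ndarray
    acquisition: dict = field(default_factory=dict)

    def __post_init__(self):
        self.raw = np.asarray(self.raw)
        if self.raw.ndim != 2:
            raise ValueError(f"thermal frame must be 2-D, got shape {self.raw.shape}")
        if self.raw.min() < 0 or self.raw.max() > 65535:
            raise ValueError("thermal counts must lie in [0, 65535]")
        self.raw = self.raw.astype(np.uint16)
        if self.shape != (IRT_HEIGHT, IRT_WIDTH):
            warnings.warn(
                f"thermal frame is {self.width}x{self.height}; the supported sensor is "
                f"{IRT_WIDTH}x{IRT_HEIGHT}",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.raw.shape

    @property
    def height(self) -> int:
        return self.raw.shape[0]

    @property
    def width(self) -> int:
        return self.raw.shape[1]


@dataclass
class TemperatureMap:
    """Per-pixel object temperature in kelvin."""

    T_object: np.ndarray

    def __post_init__(self):
        self.T_object = np.asarray(self.T_object, dtype=float)
        if not np.all(np.isfinite(self.T_object)) or np.any(self.T_object <= 0):
            raise ValueError("temperature map must be finite and positive (kelvin)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.T_object.shape


def temperature_to_raw(T, planck: PlanckConstants):
    """Forward Planck model: temperature (K) -> real-valued raw count.

    Accepts scalars or arrays; strictly increasing in ``T``.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise RadiometricDomainError(f"temperature must be positive kelvin, got {T[T <= 0].flat[0] if T.ndim else T}")
    expBT = np.exp(planck.B / T)
    if np.any(expBT <= planck.F):
        raise RadiometricDomainError(
            f"exp(B/T) <= F for T={np.max(T):g} K: temperature outside calibration domain"
        )
    raw = planck.R1 / (planck.R2 * (expBT - planck.F)) - planck.O
    return float(raw) if raw.ndim == 0 else raw


def raw_to_temperature(raw, planck: PlanckConstants):
    """Inverse Planck model: real-valued raw count -> temperature (K).

    Exact functional inverse of :func:`temperature_to_raw`.
    """
    raw = np.asarray(raw, dtype=float)
    shifted = raw + planck.O
    if np.any(shifted <= 0):
        bad = raw[shifted <= 0].flat[0] if raw.ndim else float(raw)
        raise RadiometricDomainError(
            f"raw + O <= 0 (raw={bad:g}, O={planck.O:g}): count below the calibration domain"
        )
    log_arg = planck.R1 / (planck.R2 * shifted) + planck.F
    if np.any(log_arg <= 1.0):
        bad = raw[log_arg <= 1.0].flat[0] if raw.ndim else float(raw)
        raise RadiometricDomainError(
            f"log argument <= 1 for raw={bad:g}: count above the calibration domain"
        )
    T = planck.B / np.log(log_arg)
    return float(T) if T.ndim == 0 else T


def _reflection_corrected_raw(S, settings: RadiometricSettings, planck: PlanckConstants):
    raw_reflected = temperature_to_raw(settings.T_reflected_K, planck)
    S = np.asarray(S, dtype=float)
    return (S - (1.0 - settings.emissivity) * raw_reflected) / settings.emissivity


def correct_reflection(S, settings: RadiometricSettings, planck: PlanckConstants):
    """Convert measured count(s) ``S`` to object temperature (K), removing
    the reflected ambient component.

    With ``emissivity == 1`` the reflection term vanishes and the result is
    exactly ``raw_to_temperature(S)``.
    """
    raw_object = _reflection_corrected_raw(S, settings, planck)
    if np.any(np.asarray(raw_object) + planck.O <= 0):
        raise RadiometricDomainError(
            "reflection-corrected count is below the calibration domain "
            f"(RAW_object + O <= 0) for S={np.min(np.asarray(S)):g} with "
            f"emissivity={settings.emissivity:g}, T_reflected={settings.T_reflected_K:g} K"
        )
    return raw_to_temperature(raw_object, planck)


def frame_to_temperature(
    frame: ThermalFrame, settings: RadiometricSettings, planck: PlanckConstants
) -> TemperatureMap:
    """Apply :func:`correct_reflection` to every pixel of a frame.

    A domain violation at any pixel aborts the conversion and names the
    offending pixel (x, y) rather than silently masking it: silent masking
    would bias the canopy mean.
    """
    raw_object = _reflection_corrected_raw(frame.raw, settings, planck)
    shifted = raw_object + planck.O
    bad = shifted <= 0
    if not np.any(bad):
        log_arg = planck.R1 / (planck.R2 * shifted) + planck.F
        bad = log_arg <= 1.0
    if np.any(bad):
        yy, xx = np.nonzero(bad)
        raise RadiometricDomainError(
            f"pixel (x={xx[0]}, y={yy[0]}) with raw count {int(frame.raw[yy[0], xx[0]])} "
            "is outside the radiometric calibration domain"
        )
    return TemperatureMap(raw_to_temperature(raw_object, planck))


def estimate_reflected_temperature(
    panel_frame: ThermalFrame, planck: PlanckConstants, roi: Rect
) -> float:
    """Estimate reflected ambient temperature from a low-emissivity panel frame.

    The panel acts as a diffuse reflector, so its apparent temperature
    (counts inverted with emissivity treated as 1) over the ROI estimates
    the reflected temperature. Returns the ROI mean in kelvin.
    """
    roi.validate_within(panel_frame.width, panel_frame.height)
    sl = roi.slices()
    return float(np.mean(raw_to_temperature(panel_frame.raw[sl].astype(float), planck)))
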