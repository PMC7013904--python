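"""End-to-end CWSI computation.

The crop water stress index normalizes the canopy temperature between two
references:

    CWSI = (T_canopy - T_wet) / (T_dry - T_wet)

where ``T_wet`` is the temperature of an in-scene artificial wet reference
surface (a wet cotton cloth emulating a fully transpiring leaf) and
``T_dry`` models a non-transpiring leaf as air temperature plus a
season-specific offset X (13 K in a hot/dry season, 7 K in a humid season).
CWSI ~ 0 indicates an unstressed, fully transpiring canopy; ~1 a
non-transpiring one. Values outside [0, 1] are flagged, never clamped.

Per image pair the chain is: scale the visible frame, crop the thermal
overlap, segment the canopy by GRVI, refine the mask morphologically,
radiometrically correct the thermal counts, average over the mask, and
normalize against the references. Replicate acquisitions of one treatment
are aggregated as an unweighted mean across images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidReferencesError, NoCanopyError, PipelineStageError, RoiError
from .radiometry import (
    PlanckConstants,
    RadiometricSettings,
    Rect,
    TemperatureMap,
    ThermalFrame,
    frame_to_temperature,
    kelvin_to_celsius,
)
from .registration import RegistrationParams, VisibleFrame, extract_overlap, scale_visible
from .segmentation import (
    SegmentationParams,
    grvi,
    mean_masked_temperature,
    morphological_refine,
    remove_small_regions,
    threshold_mask,
)

__all__ = [
    "ReferenceReadings",
    "CWSIRecord",
    "AcquisitionConfig",
    "ReplicateSummary",
    "compute_tdry",
    "compute_cwsi",
    "measure_wet_reference",
    "process_pair",
    "aggregate_replicates",
    "irrigation_decision",
    "X_OFFSET_HOT_SEASON",
    "X_OFFSET_WET_SEASON",
]

#: Dry-reference offsets above air temperature, by season (kelvin).
X_OFFSET_HOT_SEASON = 13.0
X_OFFSET_WET_SEASON = 7.0


@dataclass(frozen=True)
class ReferenceReadings:
    """Wet/dry reference inputs for one acquisition (kelvin).

    ``T_wet_K`` may be None when the wet reference is measured in-scene
    from a ROI; ``T_dry_K`` is always derived as ``T_air_K + X_offset_K``.
    """

    T_air_K: float
    X_offset_K: float = X_OFFSET_HOT_SEASON
    T_wet_K: Optional[float] = None

    @property
    def T_dry_K(self) -> float:
        return compute_tdry(self.T_air_K, self.X_offset_K)


@dataclass(frozen=True)
class CWSIRecord:
    """Result of processing one visible/thermal pair (temperatures in degC)."""

    image_id: str
    T_canopy_C: float
    T_wet_C: float
    T_dry_C: float
    cwsi: float
    n_canopy_pixels: int
    flags: tuple[str, ...] = ()
    group: str = ""


@dataclass(frozen=True)
class ReplicateSummary:
    """Unweighted across-image mean and standard error for one treatment."""

    n: int
    cwsi_mean: float
    cwsi_se: float
    T_canopy_C_mean: float
    T_canopy_C_se: float


@dataclass
class AcquisitionConfig:
    """Everything needed to process one acquisition batch.

    ``wet_roi`` (thermal-grid coordinates) selects in-scene wet-reference
    pixels; when absent the scalar ``references.T_wet_K`` is used.
    ``senescence_possible`` marks late-season acquisitions where the GRVI
    threshold is not validated; it adds a warning flag, not a correction.
    """

    planck: PlanckConstants
    radiometric: RadiometricSettings
    references: ReferenceReadings
    registration: RegistrationParams
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    wet_roi: Optional[Rect] = None
    senescence_possible: bool = False


def compute_tdry(T_air_K: float, X_offset_K: float) -> float:
    """Dry-reference temperature: air temperature plus the seasonal offset."""
    if T_air_K <= 0:
        raise ValueError(f"T_air must be positive kelvin, got {T_air_K}")
    if X_offset_K < 0:
        raise ValueError(f"X offset must be non-negative, got {X_offset_K}")
    return T_air_K + X_offset_K


def compute_cwsi(T_canopy: float, T_wet: float, T_dry: float) -> float:
    """(T_canopy - T_wet) / (T_dry - T_wet), unclamped.

    Invariant under a common additive shift of all three temperatures, so
    kelvin and Celsius inputs give identical values (units must agree).
    """
    if T_dry <= T_wet:
        raise InvalidReferencesError(
            f"T_dry ({T_dry:g}) must exceed T_wet ({T_wet:g}); CWSI is undefined otherwise"
        )
    return (T_canopy - T_wet) / (T_dry - T_wet)


def measure_wet_reference(T_map: TemperatureMap, wet_roi: Rect) -> float:
    """Mean corrected temperature (K) over the wet-reference ROI."""
    h, w = T_map.shape
    wet_roi.validate_within(w, h)
    sl = wet_roi.slices()
    return float(np.mean(T_map.T_object[sl]))


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except NoCanopyError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage name must be attached
        raise PipelineStageError(name, exc) from exc


def process_pair(rgb: VisibleFrame, irt: ThermalFrame, config: AcquisitionConfig,
                 image_id: str = "", group: str = "") -> CWSIRecord:
    """Run the full chain on one visible/thermal pair and return its record."""
    reg = config.registration
    scaled = _stage("scale_visible", scale_visible, rgb, reg.Sx, reg.Sy)
    overlap = _stage("extract_overlap", extract_overlap, scaled, reg)
    index_map = _stage("grvi", grvi, overlap)
    mask = _stage("threshold_mask", threshold_mask, index_map, config.segmentation.grvi_threshold)
    mask = _stage("morphological_refine", morphological_refine, mask, config.segmentation.kernel_size)
    mask = _stage("remove_small_regions", remove_small_regions, mask,
                  config.segmentation.min_region_fraction)
    T_map = _stage("frame_to_temperature", frame_to_temperature, irt, config.radiometric, config.planck)
    T_canopy_K, n_pixels = mean_masked_temperature(T_map, mask)

    if config.wet_roi is not None:
        T_wet_K = _stage("measure_wet_reference", measure_wet_reference, T_map, config.wet_roi)
    elif config.references.T_wet_K is not None:
        T_wet_K = config.references.T_wet_K
    else:
        raise InvalidReferencesError("no wet reference: provide references.T_wet_K or wet_roi")
    T_dry_K = config.references.T_dry_K
    cwsi = _stage("compute_cwsi", compute_cwsi, T_canopy_K, T_wet_K, T_dry_K)

    flags = []
    if not 0.0 <= cwsi <= 1.0:
        flags.append("cwsi_out_of_range")
    if config.senescence_possible:
        flags.append("senescence_warning")
    return CWSIRecord(
        image_id=image_id,
        T_canopy_C=kelvin_to_celsius(T_canopy_K),
        T_wet_C=kelvin_to_celsius(T_wet_K),
        T_dry_C=kelvin_to_celsius(T_dry_K),
        cwsi=cwsi,
        n_canopy_pixels=n_pixels,
        flags=tuple(flags),
        group=group,
    )


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    se = float(np.std(values, ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
    return mean, se


def aggregate_replicates(records: Sequence[CWSIRecord]) -> ReplicateSummary:
    """Unweighted mean and standard error of per-image CWSI and canopy
    temperature across replicate acquisitions (images weigh equally,
    regardless of canopy pixel count)."""
    if len(records) == 0:
        raise ValueError("cannot aggregate an empty record list")
    cwsi_mean, cwsi_se = _mean_se(np.array([r.cwsi for r in records]))
    tc_mean, tc_se = _mean_se(np.array([r.T_canopy_C for r in records]))
    return ReplicateSummary(
        n=len(records), cwsi_mean=cwsi_mean, cwsi_se=cwsi_se,
        T_canopy_C_mean=tc_mean, T_canopy_C_se=tc_se,
    )


def irrigation_decision(cwsi_mean: float, threshold: float) -> bool:
    """True (irrigate) when the treatment-mean CWSI has reached the
    configured threshold (inclusive)."""
    if not 0 < threshold <= 1:
        raise ValueError(f"CWSI threshold must be in (0, 1], got {threshold}")
    return cwsi_mean >= threshold
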