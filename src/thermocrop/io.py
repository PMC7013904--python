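"""Readers and writers for on-disk artifacts.

Formats: PNG for visible frames; 16-bit single-channel TIFF or PGM (P5,
maxval 65535) for raw thermal frames; JSON for metadata sidecars,
calibration results and exiftool-style FLIR metadata dumps; CSV for control
points, batch manifests and reports. Sidecar temperatures are kelvin (keys
suffixed ``_K``); report CSVs are degrees Celsius, the usual reporting unit.

Readers validate and reject rather than coerce; every writer's output
re-parses to an equal object.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import DimensionMismatchError, MalformedFileError, SidecarSchemaError
from .pipeline import AcquisitionConfig, CWSIRecord, ReferenceReadings
from .radiometry import (
    DEFAULT_EMISSIVITY,
    IRT_HEIGHT,
    IRT_WIDTH,
    PlanckConstants,
    RadiometricSettings,
    Rect,
    celsius_to_kelvin,
)
from .registration import ControlPointSet, RegistrationParams, VisibleFrame
from .segmentation import CanopyMask, GrviMap, SegmentationParams

__all__ = [
    "read_visible",
    "write_visible",
    "read_thermal",
    "write_thermal",
    "read_sidecar",
    "write_sidecar",
    "read_fixture_pair",
    "read_exiftool_metadata",
    "read_control_points",
    "write_control_points",
    "read_calibration",
    "write_calibration",
    "read_acquisition_config",
    "read_manifest",
    "write_report",
    "write_mask_png",
    "write_grvi_tiff",
    "REPORT_COLUMNS",
]

from .radiometry import ThermalFrame

REPORT_COLUMNS = ["image_id", "group", "n_canopy_pixels", "T_canopy_C", "T_wet_C", "T_dry_C", "CWSI", "flags"]

_PLANCK_KEYS = ("R1", "R2", "B", "O")


# ---------------------------------------------------------------- images

def read_visible(path) -> VisibleFrame:
    """Read an 8-bit RGB PNG."""
    try:
        img = Image.open(path)
        arr = np.asarray(img.convert("RGB"))
    except Exception as exc:
        raise MalformedFileError(f"cannot read visible image {path}: {exc}") from exc
    return VisibleFrame(arr)


def write_visible(frame: VisibleFrame, path) -> None:
    Image.fromarray(frame.pixels, mode="RGB").save(path, format="PNG")


def read_thermal(path, acquisition: Optional[dict] = None) -> ThermalFrame:
    """Read a raw thermal frame from 16-bit TIFF or PGM (P5, maxval 65535).

    8-bit input is rejected: the supported sensor delivers 16-bit counts.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        elif suffix == ".pgm":
            with Image.open(path) as img:
                if img.mode not in ("I", "I;16", "I;16B"):
                    raise DimensionMismatchError(
                        f"{path}: thermal PGM must be 16-bit (maxval 65535), got mode {img.mode}"
                    )
                arr = np.asarray(img)
        else:
            raise MalformedFileError(f"unsupported thermal format {suffix!r} (use .tif/.tiff/.pgm)")
    except (DimensionMismatchError, MalformedFileError):
        raise
    except Exception as exc:
        raise MalformedFileError(f"cannot read thermal image {path}: {exc}") from exc
    if arr.ndim != 2:
        raise DimensionMismatchError(f"{path}: thermal frame must be single-channel, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        raise DimensionMismatchError(f"{path}: 8-bit thermal input rejected; sensor is 16-bit raw")
    if arr.min() < 0 or arr.max() > 65535:
        raise DimensionMismatchError(f"{path}: counts outside [0, 65535]")
    return ThermalFrame(arr.astype(np.uint16), acquisition=acquisition or {})


def write_thermal(frame: ThermalFrame, path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, frame.raw)
    elif suffix == ".pgm":
        Image.fromarray(frame.raw).save(path, format="PPM")
    else:
        raise MalformedFileError(f"unsupported thermal format {suffix!r} (use .tif/.tiff/.pgm)")


def write_mask_png(mask: CanopyMask, path) -> None:
    """Export a mask for visual QC (0 background, 255 canopy)."""
    Image.fromarray((mask.M * 255).astype(np.uint8), mode="L").save(path, format="PNG")


def write_grvi_tiff(grvi_map: GrviMap, path) -> None:
    tifffile.imwrite(path, grvi_map.values.astype(np.float32))


# ---------------------------------------------------------------- sidecars

def _load_json(path) -> dict:
    try:
        with open(path, "r", encoding="utf-8") as fh:
            obj = json.load(fh)
    except json.JSONDecodeError as exc:
        raise MalformedFileError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(obj, dict):
        raise MalformedFileError(f"{path}: expected a JSON object")
    return obj


def _planck_from_mapping(obj: dict, source: str) -> PlanckConstants:
    missing = [k for k in _PLANCK_KEYS if k not in obj]
    if missing:
        raise SidecarSchemaError(f"{source}: missing required Planck key(s): {missing}")
    try:
        return PlanckConstants(
            R1=float(obj["R1"]), R2=float(obj["R2"]), B=float(obj["B"]),
            O=float(obj["O"]), F=float(obj.get("F", 1.0)),
        )
    except (TypeError, ValueError) as exc:
        raise SidecarSchemaError(f"{source}: invalid Planck constants: {exc}") from exc


def read_sidecar(path) -> dict:
    """Parse a JSON sidecar into pipeline objects.

    Required: Planck keys R1, R2, B, O (F defaults to 1) and
    ``T_reflected_K``; ``emissivity`` defaults to 0.96. Optional
    ``references`` block ({T_air_K, X_offset_K, T_wet_K}) and
    ``ground_truth`` block (passed through verbatim).

    Returns {"planck", "radiometric", "references", "ground_truth"}.
    """
    obj = _load_json(path)
    planck = _planck_from_mapping(obj, str(path))
    if "T_reflected_K" not in obj:
        raise SidecarSchemaError(f"{path}: missing required key T_reflected_K")
    try:
        radiometric = RadiometricSettings(
            emissivity=float(obj.get("emissivity", DEFAULT_EMISSIVITY)),
            T_reflected_K=float(obj["T_reflected_K"]),
        )
    except (TypeError, ValueError) as exc:
        raise SidecarSchemaError(f"{path}: invalid radiometric settings: {exc}") from exc
    references = None
    if "references" in obj:
        ref = obj["references"]
        if not isinstance(ref, dict) or "T_air_K" not in ref:
            raise SidecarSchemaError(f"{path}: references block requires T_air_K")
        references = ReferenceReadings(
            T_air_K=float(ref["T_air_K"]),
            X_offset_K=float(ref.get("X_offset_K", 13.0)),
            T_wet_K=float(ref["T_wet_K"]) if ref.get("T_wet_K") is not None else None,
        )
    return {
        "planck": planck,
        "radiometric": radiometric,
        "references": references,
        "ground_truth": obj.get("ground_truth"),
    }


def write_sidecar(path, planck: PlanckConstants, radiometric: RadiometricSettings,
                  references: Optional[ReferenceReadings] = None,
                  ground_truth: Optional[dict] = None) -> None:
    obj = {
        "R1": planck.R1, "R2": planck.R2, "B": planck.B, "F": planck.F, "O": planck.O,
        "emissivity": radiometric.emissivity, "T_reflected_K": radiometric.T_reflected_K,
    }
    if references is not None:
        obj["references"] = {
            "T_air_K": references.T_air_K,
            "X_offset_K": references.X_offset_K,
            "T_wet_K": references.T_wet_K,
        }
    if ground_truth is not None:
        obj["ground_truth"] = ground_truth
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_fixture_pair(rgb_path, irt_path, sidecar_path):
    """Read a visible/thermal/sidecar trio.

    Returns ``(VisibleFrame, ThermalFrame, sidecar_dict)``; the thermal
    frame must be the supported 320x240 sensor size.
    """
    visible = read_visible(rgb_path)
    thermal = read_thermal(irt_path)
    if thermal.shape != (IRT_HEIGHT, IRT_WIDTH):
        raise DimensionMismatchError(
            f"{irt_path}: thermal frame is {thermal.width}x{thermal.height}, "
            f"expected {IRT_WIDTH}x{IRT_HEIGHT}"
        )
    return visible, thermal, read_sidecar(sidecar_path)


# ------------------------------------------------------- exiftool adapter

_EXIF_PLANCK_TAGS = {"PlanckR1": "R1", "PlanckR2": "R2", "PlanckB": "B", "PlanckF": "F", "PlanckO": "O"}


def _parse_celsius(value) -> float:
    """Parse an exiftool temperature value: numeric degC or a '22.0 C' string."""
    if isinstance(value, (int, float)):
        return float(value)
    m = re.fullmatch(r"\s*(-?\d+(?:\.\d+)?)\s*C\s*", str(value))
    if not m:
        raise SidecarSchemaError(f"cannot parse temperature value {value!r}")
    return float(m.group(1))


def read_exiftool_metadata(json_text: str) -> tuple[PlanckConstants, RadiometricSettings]:
    """Map an exiftool-style JSON dump of FLIR tags to pipeline objects.

    Temperatures in the dump are degrees Celsius and are converted to
    kelvin. A missing Emissivity tag falls back to 0.96 with a warning.
    """
    try:
        obj = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise MalformedFileError(f"malformed exiftool JSON: {exc}") from exc
    if isinstance(obj, list):  # exiftool -j wraps results in a list
        if len(obj) != 1:
            raise MalformedFileError("exiftool JSON list must contain exactly one object")
        obj = obj[0]
    missing = [t for t in _EXIF_PLANCK_TAGS if t not in obj and t != "PlanckF"]
    if missing:
        raise SidecarSchemaError(f"missing FLIR tag(s): {missing}")
    try:
        planck = PlanckConstants(
            R1=float(obj["PlanckR1"]), R2=float(obj["PlanckR2"]), B=float(obj["PlanckB"]),
            O=float(obj["PlanckO"]), F=float(obj.get("PlanckF", 1.0)),
        )
    except (TypeError, ValueError) as exc:
        raise SidecarSchemaError(f"non-numeric FLIR Planck tag: {exc}") from exc
    if "ReflectedApparentTemperature" not in obj:
        raise SidecarSchemaError("missing FLIR tag ReflectedApparentTemperature")
    t_refl_K = celsius_to_kelvin(_parse_celsius(obj["ReflectedApparentTemperature"]))
    if "Emissivity" in obj:
        emissivity = float(obj["Emissivity"])
    else:
        warnings.warn("Emissivity tag absent; defaulting to 0.96", stacklevel=2)
        emissivity = DEFAULT_EMISSIVITY
    return planck, RadiometricSettings(emissivity=emissivity, T_reflected_K=t_refl_K)


# -------------------------------------------------------- tables and JSON

def read_control_points(path) -> ControlPointSet:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise MalformedFileError(f"cannot read control points {path}: {exc}") from exc
    return ControlPointSet(df)


def write_control_points(points: ControlPointSet, path) -> None:
    points.points.to_csv(path, index=False, lineterminator="\n")


def write_calibration(params: RegistrationParams, path) -> None:
    obj = {
        "Sx": params.Sx, "Sy": params.Sy, "bx": params.bx, "by": params.by,
        "rel_uncertainty_scale_pct": params.rel_uncertainty_scale_pct,
        "rel_uncertainty_shift_pct": params.rel_uncertainty_shift_pct,
        "n_pairs": params.n_pairs,
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_calibration(path) -> RegistrationParams:
    obj = _load_json(path)
    missing = [k for k in ("Sx", "Sy", "bx", "by") if k not in obj]
    if missing:
        raise SidecarSchemaError(f"{path}: missing calibration key(s): {missing}")
    return RegistrationParams(
        Sx=float(obj["Sx"]), Sy=float(obj["Sy"]), bx=int(obj["bx"]), by=int(obj["by"]),
        rel_uncertainty_scale_pct=float(obj.get("rel_uncertainty_scale_pct", 0.0)),
        rel_uncertainty_shift_pct=float(obj.get("rel_uncertainty_shift_pct", 0.0)),
        n_pairs=int(obj.get("n_pairs", 1)),
    )


def _parse_roi(value) -> Rect:
    if isinstance(value, (list, tuple)) and len(value) == 4:
        return Rect(*(int(v) for v in value))
    parts = str(value).split(":")
    if len(parts) != 4:
        raise SidecarSchemaError(f"ROI must be [x, y, w, h] or 'x:y:w:h', got {value!r}")
    return Rect(*(int(p) for p in parts))


def read_acquisition_config(path) -> AcquisitionConfig:
    """Read a full pipeline configuration JSON.

    Schema: Planck/radiometric keys as in :func:`read_sidecar`, plus a
    ``registration`` block ({Sx, Sy, bx, by}), an optional ``segmentation``
    block ({grvi_threshold, kernel_size, min_region_fraction}), an optional
    ``references`` block and an optional ``wet_roi``.
    """
    obj = _load_json(path)
    side = read_sidecar(path)
    if "registration" not in obj:
        raise SidecarSchemaError(f"{path}: missing registration block")
    reg = obj["registration"]
    registration = RegistrationParams(
        Sx=float(reg["Sx"]), Sy=float(reg["Sy"]), bx=int(reg["bx"]), by=int(reg["by"]),
    )
    seg = obj.get("segmentation", {})
    segmentation = SegmentationParams(
        grvi_threshold=float(seg.get("grvi_threshold", 0.04)),
        kernel_size=int(seg.get("kernel_size", 4)),
        min_region_fraction=float(seg.get("min_region_fraction", 0.1)),
    )
    references = side["references"] or ReferenceReadings(T_air_K=293.15)
    wet_roi = _parse_roi(obj["wet_roi"]) if "wet_roi" in obj else None
    return AcquisitionConfig(
        planck=side["planck"], radiometric=side["radiometric"], references=references,
        registration=registration, segmentation=segmentation, wet_roi=wet_roi,
        senescence_possible=bool(obj.get("senescence_possible", False)),
    )


def read_manifest(path) -> pd.DataFrame:
    """Read a batch manifest CSV.

    Required columns: image_id, rgb_path, irt_path, T_air_C, X_C, group;
    each row must carry either T_wet_C or wet_roi ('x:y:w:h').
    """
    try:
        df = pd.read_csv(path, dtype={"image_id": str, "group": str})
    except Exception as exc:
        raise MalformedFileError(f"cannot read manifest {path}: {exc}") from exc
    required = ["image_id", "rgb_path", "irt_path", "T_air_C", "X_C", "group"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SidecarSchemaError(f"{path}: manifest missing column(s): {missing}")
    if "T_wet_C" not in df.columns and "wet_roi" not in df.columns:
        raise SidecarSchemaError(f"{path}: manifest needs a T_wet_C or wet_roi column")
    return df


def _format_field(value) -> str:
    if isinstance(value, float):
        return f"{value:.4f}"
    return str(value)


def write_report(records: Sequence[CWSIRecord], path) -> None:
    """Write the per-image report CSV (header always present, numeric
    fields with 4 decimal places, UTF-8, LF line endings)."""
    lines = [",".join(REPORT_COLUMNS)]
    for r in records:
        row = [
            r.image_id, r.group, str(r.n_canopy_pixels),
            _format_field(float(r.T_canopy_C)), _format_field(float(r.T_wet_C)),
            _format_field(float(r.T_dry_C)), _format_field(float(r.cwsi)),
            ";".join(r.flags),
        ]
        lines.append(",".join(row))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"image_id": str, "group": str, "flags": str})
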