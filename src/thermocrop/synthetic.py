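"""Synthetic visible/thermal scene generation with known ground truth.

Emulates the field acquisition the pipeline targets: a quasi-planar green
canopy (blob-shaped leaf clusters) over brown soil, with a white wet
reference tray in scene. Thermal counts are produced by the forward
radiometric model

    S = eps * RAW(T_true) + (1 - eps) * RAW(T_reflected)

rounded to the nearest integer count, and the visible frame is rendered at
native resolution consistent with a known scale-and-shift registration
truth, so the full register -> segment -> correct -> average chain can be
exercised and checked against analytic ground truth.

Two constructions make noise-free scenes exactly recoverable:

* the ground-truth mask is defined *after* the 4x4 morphological closing
  and small-region removal that the pipeline itself applies (closing is
  idempotent, so re-applying it in the pipeline is a no-op);
* each native visible pixel takes the colour of exactly one thermal-grid
  cell, assigned so that both bilinear-interpolation neighbours of every
  scaled-overlap sample point belong to the same cell class (guaranteed
  whenever the sample spacing 1/S exceeds 2 native pixels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw

from .errors import RadiometricDomainError
from .pipeline import AcquisitionConfig, ReferenceReadings, compute_tdry
from .radiometry import (
    IRT_HEIGHT,
    IRT_WIDTH,
    PlanckConstants,
    RadiometricSettings,
    Rect,
    ThermalFrame,
    temperature_to_raw,
)
from .registration import (
    RGB_HEIGHT,
    RGB_WIDTH,
    ControlPointSet,
    RegistrationParams,
    VisibleFrame,
    round_half_away,
)
from .segmentation import CanopyMask, SegmentationParams, grvi, morphological_refine, remove_small_regions

__all__ = [
    "FIXTURE_PLANCK",
    "SceneSpec",
    "SyntheticScene",
    "generate_scene",
    "generate_control_points",
    "generate_panel_frame",
    "quantization_temperature_bound",
    "write_scene",
]

#: Typical-magnitude Planck constants for tests and fixtures (synthetic:
#: real cameras carry their own factory values in metadata).
FIXTURE_PLANCK = PlanckConstants(R1=21106.77, R2=0.012545258, B=1501.0, O=-7340.0, F=1.0)

_CLASS_SOIL, _CLASS_CANOPY, _CLASS_AWRS, _CLASS_SPECK = 0, 1, 2, 3

_GRVI_THRESHOLD = 0.04
_GRVI_MARGIN = 0.05


def _grvi_of(color) -> float:
    r, g, _ = (float(c) for c in color)
    return 0.0 if r + g == 0 else (g - r) / (g + r)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic acquisition.

    Temperatures are kelvin. Defaults describe a mildly stressed daytime
    canopy in a hot season: wet reference < canopy < sunlit soil, with
    CWSI_true = (T_canopy_mean - T_awrs) / (T_air + X - T_awrs) = 1/3.
    Noise defaults model an 8-bit colour sensor (sd 2 counts) and an
    uncooled microbolometer (sensor noise sd 0.05 K, canopy spatial
    variability sd 0.5 K).
    """

    seed: int = 0
    canopy_fraction: float = 0.6
    canopy_color: tuple[int, int, int] = (70, 110, 60)
    soil_color: tuple[int, int, int] = (120, 100, 80)
    awrs_color: tuple[int, int, int] = (230, 230, 230)
    awrs_rect: Rect = Rect(18, 18, 36, 26)
    T_canopy_mean: float = 298.15
    T_canopy_sd: float = 0.5
    T_soil: float = 306.15
    T_awrs: float = 293.15
    T_reflected: float = 293.15
    T_air: float = 295.15
    X_offset: float = 13.0
    emissivity: float = 0.96
    planck: PlanckConstants = FIXTURE_PLANCK
    registration_truth: RegistrationParams = field(
        default_factory=lambda: RegistrationParams(Sx=0.367, Sy=0.375, bx=219, by=189)
    )
    color_noise_sd: float = 2.0
    thermal_noise_sd: float = 0.05
    n_distractor_specks: int = 0

    def __post_init__(self):
        if not 0 < self.canopy_fraction < 1:
            raise ValueError(f"canopy_fraction must be in (0, 1), got {self.canopy_fraction}")
        if _grvi_of(self.canopy_color) < _GRVI_THRESHOLD + _GRVI_MARGIN:
            raise ValueError(
                f"canopy colour GRVI {_grvi_of(self.canopy_color):.3f} too close to the "
                f"threshold {_GRVI_THRESHOLD}"
            )
        if _grvi_of(self.soil_color) > _GRVI_THRESHOLD - _GRVI_MARGIN:
            raise ValueError(
                f"soil colour GRVI {_grvi_of(self.soil_color):.3f} too close to the "
                f"threshold {_GRVI_THRESHOLD}"
            )
        if not self.T_awrs < self.T_canopy_mean < self.T_soil:
            raise ValueError(
                "expected daytime ordering T_awrs < T_canopy_mean < T_soil, got "
                f"{self.T_awrs}, {self.T_canopy_mean}, {self.T_soil}"
            )
        self.awrs_rect.validate_within(IRT_WIDTH, IRT_HEIGHT)

    @property
    def T_dry(self) -> float:
        return compute_tdry(self.T_air, self.X_offset)

    @property
    def cwsi_true(self) -> float:
        return (self.T_canopy_mean - self.T_awrs) / (self.T_dry - self.T_awrs)


@dataclass
class SyntheticScene:
    """A generated fixture pair plus its ground truth."""

    spec: SceneSpec
    visible: VisibleFrame
    thermal: ThermalFrame
    mask_true: CanopyMask
    ground_truth: dict

    def true_config(self) -> AcquisitionConfig:
        """Pipeline configuration matching the generating parameters
        (wet reference taken in-scene from the tray ROI)."""
        return AcquisitionConfig(
            planck=self.spec.planck,
            radiometric=RadiometricSettings(
                emissivity=self.spec.emissivity, T_reflected_K=self.spec.T_reflected
            ),
            references=ReferenceReadings(T_air_K=self.spec.T_air, X_offset_K=self.spec.X_offset),
            registration=self.spec.registration_truth,
            segmentation=SegmentationParams(),
            wet_roi=self.spec.awrs_rect,
        )


def _canopy_blob_mask(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Union of three random ellipses ('leaf clusters'), kept clear of the
    frame border and of the wet-reference tray (3 px guard so the closing
    cannot invade it)."""
    target_total = spec.canopy_fraction * IRT_WIDTH * IRT_HEIGHT
    per_blob = target_total / 3.0
    mask = np.zeros((IRT_HEIGHT, IRT_WIDTH), dtype=bool)
    margin = 8
    for _ in range(3):
        elong = rng.uniform(0.7, 1.4)
        r_base = np.sqrt(per_blob / np.pi)
        a, b = r_base * elong, r_base / elong
        rot = rng.uniform(0, np.pi)
        rmax = max(a, b)
        cy = rng.uniform(margin + rmax, IRT_HEIGHT - margin - rmax)
        cx = rng.uniform(margin + rmax, IRT_WIDTH - margin - rmax)
        rr, cc = draw.ellipse(cy, cx, a, b, shape=(IRT_HEIGHT, IRT_WIDTH), rotation=rot)
        mask[rr, cc] = True
    guard = spec.awrs_rect
    y0, x0 = max(guard.y - 3, 0), max(guard.x - 3, 0)
    mask[y0 : guard.y + guard.height + 3, x0 : guard.x + guard.width + 3] = False
    return mask


def _place_specks(cls: np.ndarray, n: int, rng: np.random.Generator) -> None:
    """Paint n 2x2 distractor specks of canopy colour (class SPECK) on soil,
    at least 8 px from canopy and 4 px from the tray. The specks exist only
    in the visible rendering; thermally they remain soil."""
    if n == 0:
        return
    canopy = cls == _CLASS_CANOPY
    awrs = cls == _CLASS_AWRS
    near_canopy = ndimage.binary_dilation(canopy, structure=np.ones((17, 17), bool))
    near_awrs = ndimage.binary_dilation(awrs, structure=np.ones((9, 9), bool))
    allowed = (cls == _CLASS_SOIL) & ~near_canopy & ~near_awrs
    allowed[-2:, :] = False
    allowed[:, -2:] = False
    ys, xs = np.nonzero(allowed)
    if len(ys) < n:
        raise ValueError("not enough clear soil to place distractor specks")
    for idx in rng.choice(len(ys), size=n, replace=False):
        y, x = ys[idx], xs[idx]
        cls[y : y + 2, x : x + 2] = _CLASS_SPECK


def _cell_ownership(n_native: int, n_out: int) -> np.ndarray:
    """Map each native pixel index to the scaled-grid cell whose bilinear
    sample may touch it; pixels no sample touches get their nearest cell.

    Requires the sample spacing n_native/n_out > 2 so that the two
    interpolation neighbours of distinct output pixels never collide.
    """
    s = n_out / n_native
    if 1.0 / s <= 2.0:
        raise ValueError("scale too coarse: native/scaled sample spacing must exceed 2 px")
    u = np.arange(n_native)
    owner = np.clip(np.floor((u + 0.5) * s - 0.5 + 0.5).astype(int), 0, n_out - 1)
    X = np.arange(n_out)
    u_star = (X + 0.5) / s - 0.5
    lo = np.clip(np.floor(u_star).astype(int), 0, n_native - 1)
    hi = np.clip(lo + 1, 0, n_native - 1)
    owner[lo] = X
    owner[hi] = X
    return owner


def _render_visible(cls_irt: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> VisibleFrame:
    reg = spec.registration_truth
    out_w = round_half_away(RGB_WIDTH * reg.Sx)
    out_h = round_half_away(RGB_HEIGHT * reg.Sy)
    ext = np.full((out_h, out_w), _CLASS_SOIL, dtype=np.uint8)
    ext[reg.by : reg.by + IRT_HEIGHT, reg.bx : reg.bx + IRT_WIDTH] = cls_irt
    col_owner = _cell_ownership(RGB_WIDTH, out_w)
    row_owner = _cell_ownership(RGB_HEIGHT, out_h)
    cls_native = ext[np.ix_(row_owner, col_owner)]
    palette = np.array(
        [spec.soil_color, spec.canopy_color, spec.awrs_color, spec.canopy_color], dtype=float
    )
    pixels = palette[cls_native]
    if spec.color_noise_sd > 0:
        pixels = pixels + rng.normal(0.0, spec.color_noise_sd, size=pixels.shape)
    pixels = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        return VisibleFrame(pixels)


def _forward_counts(T_true: np.ndarray, spec: SceneSpec) -> np.ndarray:
    raw_true = temperature_to_raw(T_true, spec.planck)
    raw_refl = temperature_to_raw(spec.T_reflected, spec.planck)
    S = spec.emissivity * raw_true + (1.0 - spec.emissivity) * raw_refl
    S = np.rint(S)
    if S.min() < 0 or S.max() > 65535:
        raise RadiometricDomainError(
            f"forward-model counts outside the 16-bit range ([{S.min():g}, {S.max():g}])"
        )
    return S.astype(np.uint16)


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Generate one deterministic fixture pair with ground truth.

    The ground-truth mask is closing- and removal-stable, so running the
    standard segmentation chain on a noise-free rendering reproduces it
    exactly; `ground_truth["cwsi_true"]` is the analytic index computed
    from the generating temperatures.
    """
    rng = np.random.default_rng(spec.seed)
    blobs = _canopy_blob_mask(spec, rng)
    mask_true = remove_small_regions(
        morphological_refine(CanopyMask(blobs.astype(np.uint8)), 4), 0.1
    )

    cls = np.full((IRT_HEIGHT, IRT_WIDTH), _CLASS_SOIL, dtype=np.uint8)
    cls[mask_true.M.astype(bool)] = _CLASS_CANOPY
    sl = spec.awrs_rect.slices()
    cls[sl] = _CLASS_AWRS
    _place_specks(cls, spec.n_distractor_specks, rng)

    T_true = np.full((IRT_HEIGHT, IRT_WIDTH), spec.T_soil, dtype=float)
    canopy_sel = cls == _CLASS_CANOPY
    T_true[canopy_sel] = spec.T_canopy_mean + rng.normal(
        0.0, spec.T_canopy_sd, size=int(canopy_sel.sum())
    )
    T_true[cls == _CLASS_AWRS] = spec.T_awrs
    if spec.thermal_noise_sd > 0:
        T_true = T_true + rng.normal(0.0, spec.thermal_noise_sd, size=T_true.shape)

    visible = _render_visible(cls, spec, rng)
    thermal = ThermalFrame(
        _forward_counts(T_true, spec),
        acquisition={"viewing_angle_deg": 60.0, "object_distance_m": 3.0},
    )
    ground_truth = {
        "T_canopy_mean_K": spec.T_canopy_mean,
        "T_soil_K": spec.T_soil,
        "T_wet_K": spec.T_awrs,
        "T_air_K": spec.T_air,
        "X_offset_K": spec.X_offset,
        "T_dry_K": spec.T_dry,
        "cwsi_true": spec.cwsi_true,
        "canopy_area_px": mask_true.area,
    }
    return SyntheticScene(
        spec=spec, visible=visible, thermal=thermal, mask_true=mask_true, ground_truth=ground_truth
    )


def generate_control_points(
    truth: RegistrationParams, n_pairs: int = 50, n_points: int = 8,
    noise_sd: float = 0.0, seed: int = 0,
) -> ControlPointSet:
    """Simulate manual control-point selection over n_pairs image pairs.

    Points are exactly consistent with the registration truth; Gaussian
    selection noise (sd in pixels) is added independently to every
    coordinate in both frames.
    """
    if n_pairs < 1:
        raise ValueError(f"n_pairs must be >= 1, got {n_pairs}")
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2 (scale + shift), got {n_points}")
    rng = np.random.default_rng(seed)
    rows = []
    for pair in range(n_pairs):
        x = rng.uniform(10, IRT_WIDTH - 10, size=n_points)
        y = rng.uniform(10, IRT_HEIGHT - 10, size=n_points)
        u = (x + truth.bx) / truth.Sx
        v = (y + truth.by) / truth.Sy
        if noise_sd > 0:
            u = u + rng.normal(0, noise_sd, n_points)
            v = v + rng.normal(0, noise_sd, n_points)
            x = x + rng.normal(0, noise_sd, n_points)
            y = y + rng.normal(0, noise_sd, n_points)
        for k in range(n_points):
            rows.append((pair, u[k], v[k], x[k], y[k]))
    df = pd.DataFrame(rows, columns=["pair_id", "u_rgb", "v_rgb", "x_irt", "y_irt"])
    return ControlPointSet(df)


def generate_panel_frame(
    T_reflected: float, noise_sd: float, planck: PlanckConstants, seed: int = 0
) -> ThermalFrame:
    """A uniform reflector-panel frame whose counts encode the apparent
    temperature T_reflected (emissivity-1 path) plus sensor noise.

    Counts falling outside the 16-bit range raise rather than clip
    silently: a clipped panel would bias the reflected-temperature
    estimate.
    """
    rng = np.random.default_rng(seed)
    T = np.full((IRT_HEIGHT, IRT_WIDTH), float(T_reflected))
    if noise_sd > 0:
        T = T + rng.normal(0.0, noise_sd, size=T.shape)
    S = np.rint(temperature_to_raw(T, planck))
    if S.min() < 0 or S.max() > 65535:
        raise RadiometricDomainError(
            f"panel counts outside the 16-bit range ([{S.min():g}, {S.max():g}]) "
            f"for T_reflected={T_reflected:g} K"
        )
    return ThermalFrame(S.astype(np.uint16))


def quantization_temperature_bound(
    planck: PlanckConstants, emissivity: float, T_min: float = 280.0, T_max: float = 320.0
) -> float:
    """Worst-case temperature error induced by rounding forward-model
    counts to integers, over [T_min, T_max]: 0.5 / (eps * dRAW/dT),
    maximized where the count-temperature slope is shallowest."""
    T = np.linspace(T_min, T_max, 401)
    expBT = np.exp(planck.B / T)
    draw_dT = planck.R1 * planck.B * expBT / (planck.R2 * (expBT - planck.F) ** 2 * T**2)
    return float(np.max(0.5 / (emissivity * draw_dT)))


def write_scene(scene: SyntheticScene, outdir) -> dict:
    """Write a scene as fixture files: rgb.png, irt.tif, sidecar.json
    (with references and ground truth) and mask.png; returns the paths."""
    from . import io as tio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "rgb": outdir / "rgb.png",
        "irt": outdir / "irt.tif",
        "sidecar": outdir / "sidecar.json",
        "mask": outdir / "mask.png",
    }
    tio.write_visible(scene.visible, paths["rgb"])
    tio.write_thermal(scene.thermal, paths["irt"])
    tio.write_mask_png(scene.mask_true, paths["mask"])
    spec = scene.spec
    tio.write_sidecar(
        paths["sidecar"],
        planck=spec.planck,
        radiometric=RadiometricSettings(emissivity=spec.emissivity, T_reflected_K=spec.T_reflected),
        references=ReferenceReadings(
            T_air_K=spec.T_air, X_offset_K=spec.X_offset, T_wet_K=spec.T_awrs
        ),
        ground_truth={**scene.ground_truth, "mask_path": paths["mask"].name},
    )
    return paths
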