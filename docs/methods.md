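# Methods

## Model and assumptions

**Radiometry.** The camera model is the standard single-band Planck-form
calibration: raw count `RAW(T) = R1/(R2·(exp(B/T) − F)) − O`, strictly
increasing in T, with per-camera constants `R1, R2, B, F, O` taken from
camera metadata (the exiftool-tag adapter in `thermocrop.io` maps the usual
FLIR tag names). Two radiance components reach the detector: emission from
the object, weighted by its emissivity ε, and reflected ambient radiation,
weighted by 1 − ε. The correction assumes a constant, wavelength-independent
ε over the sensor's band (reasonable for the ~6 µm band of long-wave
microbolometers and ε = 0.96 for leaves) and no atmospheric transmission
loss — valid at the short working distances (~3 m) of handheld acquisition,
and deliberately not modelled. F defaults to 1 when metadata omits it, the
common published parameterization. Temperatures are kelvin everywhere
internally; report CSVs are °C.

A pixel whose reflection-corrected count leaves the calibration domain
(`RAW_object + O ≤ 0` or a log argument ≤ 1) aborts the conversion with the
pixel named, rather than being masked silently: silently dropping pixels
would bias the canopy mean in exactly the situations (hot soil, specular
reflections) where the data are already suspect.

**Reflected temperature.** The reflector method is used: a frame of a
low-emissivity uniform panel is converted with ε treated as 1 and averaged
over a user ROI. This is the simplest standard procedure; other
manual-specified variants (multi-frame averaging, crumpled-foil panels)
would slot into the same `estimate_reflected_temperature` interface.

**Registration.** The geometric model is axis-aligned scale plus integer
shift — no rotation or shear. The two sensors are rigidly mounted, so
rotation residuals behave as noise in the manually picked control points
and are absorbed by the across-pair averaging. Each image pair is fitted
separately per axis by ordinary least squares (`x_irt = Sx·u_rgb − bx`);
robust estimators are unnecessary for hand-picked points. The reported
(bx, by) is the across-pair mean rounded half away from zero: the mask only
localizes canopy, and sub-pixel window placement is immaterial at the
granularity of a vegetation-index mask. (bx, by) is expressed in
scaled-visible pixels (the thermal window origin); with the default
calibration the 320 × 240 window at (219, 189) sits inside the 752 × 576
scaled frame. Bilinear resampling maps output pixel centre X to input
coordinate `(X + 0.5)·W_in/W_out − 0.5` with edge clamping, and the target
size is `round(W·Sx) × round(H·Sy)` (half away from zero; the rounding rule
is a package convention). Thermal data is never interpolated.

**Segmentation.** GRVI is computed on the overlap crop; black pixels
(R + G = 0) get the sentinel 0 and are never canopy. The threshold
comparison is inclusive (GRVI ≥ τ, default τ = 0.04 — validated for green,
pre-senescence canopies only; a senescence flag can be attached to records
but no correction is attempted). Refinement is one morphological closing:
dilation then erosion with the same 4 × 4 all-ones element. An even element
has no centre pixel, so the anchor is fixed at the upper-left pixel of the
central 2 × 2 block, and both passes treat out-of-frame pixels as
background; the slight erosion of structures touching the frame border is
accepted and tested. Components are 8-connected (diagonal leaf structures
must not fragment), and the small-region rule deletes components smaller
than 1/10 of the *foreground* area of the post-closing mask, judged once
against the pre-removal total (a frame-relative reading — anything under
7680 px — would delete essentially all real canopy components and is
rejected as implausible).

**CWSI.** `CWSI = (T_canopy − T_wet)/(T_dry − T_wet)`, invariant under a
common additive shift of its three inputs (so °C and K give the same
value). It is not clamped: values outside [0, 1] are physically
informative (e.g. canopy cooler than the wet reference) and are flagged
`cwsi_out_of_range` instead. T_wet comes either from an in-scene wet
reference ROI mean or from an external scalar; T_air is always an external
scalar (weather station), and the season-specific X offset is
configuration, never inferred. Replicate aggregation weights images
equally (not by canopy pixel count), matching treatment-level averaging of
per-image means; the standard error of a single record is reported as 0.
The irrigation decision is inclusive: irrigate when the mean has *reached*
the threshold.

## Tunable parameters

| parameter | default | units | notes |
|---|---|---|---|
| ε (emissivity) | 0.96 | — | leaves; constant across the season |
| GRVI threshold τ | 0.04 | — | pre-senescence canopies |
| closing kernel | 4 × 4 | px | fixed sensor size makes one size workable |
| min region fraction | 0.1 | — | of pre-removal foreground area |
| X offset (hot / wet season) | 13 / 7 | K | added to T_air for T_dry |
| (Sx, Sy), (bx, by) | 0.367, 0.375, 219, 189 | —, px | per sensor pair; recalibrate with `calibrate` |
| CWSI irrigation threshold | 0.4 or 0.7 | — | treatment policy, not a pipeline constant |

## Synthetic scenes: what they emulate, and what they do not

The generator renders a quasi-planar canopy (a union of three random
ellipses mimicking leaf clusters — no botanical realism claimed) over soil,
with a white wet-reference tray, at the native visible resolution and
consistent with a known registration truth; thermal counts follow the
forward model `S = ε·RAW(T_true) + (1 − ε)·RAW(T_reflected)` rounded to
integer counts. Default noise: colour sd 2 counts (8-bit sensor), thermal
sensor noise sd 0.05 K (uncooled-microbolometer NETD class), canopy spatial
variability sd 0.5 K. The worst-case temperature error induced by count
rounding, `0.5/(ε·dRAW/dT)`, is computed by
`quantization_temperature_bound` and is ≈ 0.0034 K for the fixture
constants — below the 0.05 K sensitivity class of the emulated sensor.

Two constructions make noise-free scenes *exactly* recoverable, which turns
the whole chain into a checkable identity:

- the ground-truth mask is defined after applying the same closing and
  small-region removal the pipeline uses; closing is idempotent, so the
  pipeline's refinement is a no-op on a perfectly thresholded mask;
- each native visible pixel is coloured by exactly one thermal-grid cell,
  with cell ownership chosen so that both bilinear-interpolation neighbours
  of every scaled-overlap sample point share one class. This is possible
  whenever the sample spacing 1/S exceeds 2 native pixels (true for the
  supported sensor pair, 1/0.367 ≈ 2.7) and removes class mixing at blob
  boundaries.

What passing on these scenes does **not** show: robustness to senescent or
yellowing canopies (GRVI fails there by design), viewing-angle and
mixed-pixel effects at leaf edges, wind-blurred acquisitions, lens
distortion, or real FLIR binary metadata parsing (metadata arrives
pre-extracted as JSON). Field performance must be established against
in-situ references (e.g. thermocouples), which is outside this package.

## Numerical choices and degenerate inputs

- Roundtrip count ↔ temperature is exact to ≤ 1e-9 K over 250–350 K; the
  inversion is the closed-form inverse, no iteration.
- Degenerate control points (no spread on an axis) raise a singular-fit
  error; fewer than 2 points per pair is rejected.
- An empty refined mask raises a distinct "no canopy detected" error — never
  0/0.
- T_dry ≤ T_wet raises an invalid-references error (CWSI undefined).
- Counts are pure unsigned 16-bit integers; any sensor gain is assumed
  folded into the Planck constants. 8-bit thermal files are rejected.
- Forward-model counts outside [0, 65535] raise rather than clip: a clipped
  fixture would silently bias its own ground truth.

## Problem sizes used in the checks

Acceptance-style checks run at the instrument's native sizes (2048 × 1536
visible, 320 × 240 thermal): 50 calibration pairs × 8 control points for
registration recovery, 20 scenes each for segmentation fidelity and the
CWSI sweep (true CWSI 0.1–0.9), and a 50-pair batch run for determinism —
the batch size the tool is specified to handle in a single run. The
morphology oracle comparison uses 100 random 32 × 24 masks, where a
pixel-loop closing is affordable.

## Known limitations

- The GRVI threshold and the whole segmentation stage assume a green
  canopy; senescence produces under-segmentation that no flag can repair.
- Sub-pixel leaf fraction within a thermal pixel is not modelled; thermal
  pixels at canopy borders mix leaf and soil radiance.
- The scale+shift registration ignores parallax, so the calibration holds
  only near the acquisition distance at which it was performed.
- The dry reference is an empirical offset above air temperature, not an
  energy-balance model; the offset is season- and climate-specific
  configuration.
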