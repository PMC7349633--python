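# Methods

This note documents the models and procedures `spadmap` implements, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical decisions that affect results.

## Sensor model

The reference profile describes a snapshot-mosaic VNIR sensor: 25
narrow-band filters tiled in a 5×5 pattern on the focal plane, band
centers 666–945 nm, FWHM widening from 3.35 nm (red) to 12.10 nm (long
NIR), 10-bit gray resolution, 409×217 pixels per decoded band. Two
adjacent bands at 887 and 888 nm are physically distinct filters; both
are addressable by exact wavelength, and band lookup never interpolates.
The mosaic layout (which tile position carries which band) is sensor
firmware-specific; the default maps the ascending wavelength list
row-major onto the tile and can be overridden in the profile file.

## Reflectance calibration

Gray level and reflectance are both linear in radiance, so a per-band
affine law `R_λ = a_λ G_λ + b_λ` is fitted by ordinary least squares on
the four panels of a standard board (nominal reflectances 1.0, 0.75, 0.5,
0). Panel gray levels are rectangle means supplied by configuration (the
original acquisition software selects them interactively). Calibrated
values are **not clipped**: clipping negatives (which arise under noise
for panels near zero) would bias masked means upward. Negatives are
counted and logged instead. Illumination drift between recalibrations is
out of scope; one model applies to one cube.

## Segmentation: MDVI–OTSU–CDL

`MDVI(α) = I_888 − α·I_681` with default α = 2.5, the empirically optimal
modified coefficient for potato against soil/film/straw backgrounds. The
chain is: MDVI → clip negatives to 0 → min–max rescale to 256 integer
levels (half-up rounding) → Otsu threshold (exhaustive between-class
variance over t = 0..254, ties to the lowest t) → foreground strictly
above t → 3×3 binary median filter (edge replication) → keep the largest
connected domain (8-connectivity default; equal-area ties keep the
component whose first pixel comes first in raster order).

Clipping negative MDVI before rescaling is deliberate. Negative values
mark film, board panels and dark soil and carry no vegetation signal; the
saturating uint8 arithmetic of the original implementation discards them
implicitly. Keeping them (available via `clip_negative=False`) lets
strongly negative film/board pixels stretch the rescale so far that soil
lands near the plant cluster, and Otsu's variance criterion then splits
film-against-rest instead of plant-against-background — the chain fails
even on noise-free scenes. With the clip the index histogram is a
background spike at 0 plus a plant mode, which is the regime Otsu
handles well.

The median filter runs once (iterating is a stability experiment, not
part of the chain). CDL's known failure mode is kept intentionally: if a
weed is larger than the target plant, the weed wins; the method is a
single-plant extractor by design.

## UVE–PLS SPAD model

- **SPXY split** (default 2:1): distances `d(i,j) = d_x/max d_x +
  d_y/max d_y` with Euclidean spectral distance and |ΔSPAD|; the seed
  pair maximizes the joint distance, then samples are added greedily by
  max–min distance until the calibration set holds ⌈2n/3⌉ samples (100
  samples → 67/33). All ties resolve to the lowest sample index, so the
  split is deterministic and permutation-stable up to exact ties.
- **PLS1**: mean-centered NIPALS (scikit-learn backend), no unit-variance
  scaling by default — reflectance bands share a scale, and autoscaling
  inflates noisy bands; a `scale` flag enables it. Component count is
  chosen by leave-one-out RMSECV, capped at min(n−2, p, 15), ties to the
  smaller count.
- **UVE**: the reliability index of band j is the mean over leave-one-out
  refits of its PLS coefficient divided by the standard deviation (ddof
  1) over refits; bands with |RI| ≥ threshold (default 1.0) are retained.
  A coefficient with zero spread and nonzero mean gives RI = ±∞ and is
  always retained. Because jackknife fold spread scales like SE/√n, RI
  grows like √n times a t-statistic, so a fixed threshold of 1.0 is
  permissive at realistic n — it reproduces the published *usage*, not a
  scale-free criterion. For scale-adaptive selection the classic
  noise-augmented variant is available (`noise_augment=True`): p
  artificial noise columns of negligible magnitude (~1e-10) are appended
  and the cutoff becomes the maximum |RI| over them. The property suites
  that assert noise-band rejection use this variant.
- **Metrics**: R² = 1 − SSE/SST, RMSE = √(SSE/n) (population n, not
  n−1), RPD = Std/RMSE with Std the sample standard deviation (ddof 1) of
  the reference values unless a reference deviation is supplied. Grades:
  RPD > 2 good, 1.4 ≤ RPD ≤ 2 middle, < 1.4 poor.
- The training pipeline selects the component count on the full spectrum,
  runs UVE with it, re-selects on the retained bands, and refits — the
  reduced band set generally supports fewer latent components.

The shipped published model is a ten-term linear model on reflectance at
681, 816, 827, 837, 849, 859, 869, 888, 910 and 935 nm with intercept
43.828 SPAD. The wavelength list accompanying its original description
elsewhere names 706 nm instead of 827 nm; the coefficients as printed are
authoritative here and are carried verbatim.

## Per-pixel mapping

Prediction is the sparse linear form Y = Σ c_j R(λ_j) + intercept applied
independently per masked pixel, so the map restricted to any sub-mask
equals pixel-wise prediction, and the mean of predictions equals the
prediction of the mean spectrum (used as a cross-check in tests).
Predictions are not clamped to physical SPAD bounds; only rendering
clamps, to the display range (default 0–60 SPAD). The color ramp is a
fixed 256-entry blue → green → yellow lookup, channel-wise monotone, with
background forced to the blue endpoint.

## Synthetic scenes

`generate_scene` paints, back-to-front: soil background, a mulch-film
strip, residual straw, the 4-level board, a weed, a neighboring plant,
and the target plant, using piecewise-linear spectral templates with a
small per-object amplitude jitter (sd 3%). The templates encode the field
contrasts: plants/weeds have red reflectance < 0.15 and an NIR plateau
> 0.5; film is uniformly 0.7; soil 0.08–0.14; straw ~0.35. Gray cubes
are derived by a per-band affine map (default G = 800·R + 100) with
half-up rounding to 10 bits; reflectance noise (default 0; 0.01 for the
"noisy" study conditions, ~1% shot noise) is added before quantization.
The noiseless truth cube, painted plant mask, board rectangles (panel
interiors) and per-pixel SPAD field travel with the scene.

Two constructions make ground truth exactly recoverable:

- plant/weed/neighbor outlines are iterated to a fixed point of the 3×3
  binary majority filter before painting — a canopy boundary smooth at
  sensor resolution — so the noiseless chain returns the painted mask
  bit-for-bit rather than eroding its corners;
- the SPAD field (a left-to-right ramp of ±3 SPAD around the base
  spectrum's model value) perturbs the spectrum only along a direction
  supported on the published-model bands outside 681/888 nm with unit
  model response, so the field is exactly invertible by the shipped model
  while the vegetation index is untouched. Segmentation and SPAD truth
  are decoupled by construction.

The film strip (~30% of the frame) is deliberately larger than the plant
(~10%): at α = 0.5 the film stays in the Otsu foreground and CDL keeps
it, collapsing accuracy — the documented low-coefficient failure mode.
At α ≥ 1 all background is removed in these scenes; reproducing the
*high*-α failure (plant pixels mistakenly discarded) would need
within-canopy spectral variability the templates keep mild.

What the generator does **not** emulate: radiative transfer, BRDF and
illumination geometry, mixed boundary pixels, canopy self-shadowing, and
spatially correlated noise. Passing tests therefore demonstrate the
correctness of the algorithms under the stated contrasts, not field-level
accuracy; the published field accuracies depend on field data this
package does not ship.

`generate_spectra_dataset` draws per-plant mean spectra either from three
latent factors (amplitude, red absorption depth, NIR tilt — correlated,
smooth, realistic for canopy means) or as independent noisy bands (the
classic variable-selection benchmark). SPAD is exactly linear in the
delivered reflectance (weights on 681/888/935 nm at −50/+20/+20 by
default, intercept 12.6, noise σ = 1 SPAD), spanning roughly SPAD 17–53
as in field datasets. Reflectance is floored at 0 before the response is
computed, so the linear relation is exact on the delivered matrix.

## Problem sizes and numerics

Tests and the acceptance script run scenes at 96×160 (same layout,
scaled) and spectra at n = 100–200; the full 217×409 geometry is
exercised by the examples. Otsu agreement with the exhaustive oracle,
flood-fill component agreement, and full-rank PLS-vs-OLS equivalence
(tolerance 1e-8) are checked on randomized batches with fixed seeds. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; rerunning any generator with the same seed is
bit-identical.

## Known limitations

- Single-plant extraction by construction; no instance segmentation.
- The fixed UVE threshold is scale-dependent (see above); prefer the
  noise-augmented cutoff when n varies.
- Calibration assumes the board and scene share illumination; drift
  within an acquisition window is not modeled.
- MIoU is computed against whatever reference mask is supplied; the
  package does not create reference masks.
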