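"""Seeded synthetic field scenes and spectra datasets.

Every downstream stage (calibration, segmentation, chemometrics, mapping)
is testable without a camera: :func:`generate_scene` paints a 25-band plot
scene — soil background, a mulch-film strip, residual straw, a 4-level
standard board, a weed, a neighboring plant, and the target plant — with
spectral signatures that reproduce the qualitative field contrasts (plants:
low red / high NIR; film: uniformly high; soil: uniformly low), and returns
ground truth alongside: the noiseless reflectance cube, the painted plant
mask, the board reading rectangles, and a per-pixel SPAD field.

Signatures are piecewise-linear templates with a small per-scene amplitude
jitter, not radiative-transfer output: enough to exercise the sign
structure of the vegetation index, not photorealism.

Two constructions make ground truth exactly recoverable:

* plant/weed/neighbor blobs are iterated to a fixed point of the 3x3
  binary majority (median) filter before painting, i.e. the canopy outline
  is smooth at sensor resolution, so the noiseless segmentation chain
  returns the painted mask bit-for-bit;
* the per-pixel SPAD field perturbs the plant spectrum only along a
  direction supported on the published-model bands *outside* 681/888 nm,
  so the field is exactly invertible by the shipped ten-term model while
  the vegetation index (681/888 nm) is untouched.

:func:`generate_spectra_dataset` draws per-plant mean-reflectance tables
with a known linear SPAD relation for model-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import BOARD_LEVELS, Rect
from .cube import BinaryMask, SpectralCube
from .chemometrics import SpectraTable
from .errors import BadLayout
from .mapping import SpadModel, load_published_model
from .sensor import SensorProfile, reference_profile

__all__ = [
    "SceneObject",
    "SceneSpec",
    "SceneBundle",
    "default_signatures",
    "default_objects",
    "generate_scene",
    "generate_spectra_dataset",
    "DEFAULT_GRAY_MODEL",
    "DEFAULT_SCENE_NOISE_SD",
]

#: Per-band affine reflectance -> grayscale map (slope, offset), 10-bit safe.
DEFAULT_GRAY_MODEL: tuple[float, float] = (800.0, 100.0)

#: Reflectance noise used by the "noisy scene" study conditions (~1 percent,
#: typical snapshot-sensor shot noise at field exposure).
DEFAULT_SCENE_NOISE_SD: float = 0.01

_TEMPLATES: dict[str, list[tuple[float, float]]] = {
    # (wavelength nm, reflectance) nodes, linearly interpolated.
    "plant": [(666, 0.05), (681, 0.05), (706, 0.10), (720, 0.30),
              (746, 0.50), (772, 0.65), (945, 0.65)],
    "weed": [(666, 0.07), (681, 0.07), (706, 0.11), (720, 0.28),
             (746, 0.46), (772, 0.58), (945, 0.58)],
    "neighbor_plant": [(666, 0.055), (681, 0.055), (706, 0.10), (720, 0.29),
                       (746, 0.48), (772, 0.62), (945, 0.62)],
    "film": [(666, 0.70), (945, 0.70)],
    "soil": [(666, 0.08), (945, 0.14)],
    "straw": [(666, 0.33), (945, 0.37)],
}


def default_signatures(profile: SensorProfile) -> dict[str, np.ndarray]:
    """Reflectance signature per object kind, sampled at the profile bands.

    Plants/weeds: red (666/681 nm) below 0.15 with a NIR plateau above 0.5;
    film: uniformly >= 0.6; soil: uniformly <= 0.2; straw intermediate flat.
    The board is handled separately (its panels are the nominal gray levels).
    """
    wl = np.asarray(profile.wavelengths)
    return {
        kind: np.interp(wl, [n for n, _ in nodes], [r for _, r in nodes])
        for kind, nodes in _TEMPLATES.items()
    }


@dataclass
class SceneObject:
    """One painted object: ``kind`` plus geometry.

    Geometry is ``{"type": "full"}`` (background), ``{"type": "rect",
    "rect": (row, col, h, w)}``, or ``{"type": "ellipse", "center": (r, c),
    "semi": (a, b)}``.
    """

    kind: str
    geometry: dict


@dataclass
class SceneSpec:
    """Deterministic recipe for one synthetic scene.

    ``gray_model`` is the inverse of the calibration law: per-band
    G = slope * R + offset, quantized to the sensor bit depth.
    ``spad_amplitude`` is the half-range (SPAD units) of the plant's
    left-to-right SPAD ramp around the spectrum's model-implied value.
    """

    seed: int
    shape: tuple[int, int] = (217, 409)
    noise_sd: float = 0.0
    gray_model: tuple[float, float] = DEFAULT_GRAY_MODEL
    spad_amplitude: float = 3.0
    signature_jitter_sd: float = 0.03
    objects: list[SceneObject] | None = None
    profile: SensorProfile = field(default_factory=reference_profile)


@dataclass
class SceneBundle:
    """A generated scene with every piece of ground truth it was built from."""

    cube_grayscale: SpectralCube
    cube_reflectance_truth: SpectralCube
    plant_mask_truth: BinaryMask
    board_boxes: list[Rect]
    spad_truth: np.ndarray
    table_truth: dict[str, np.ndarray]
    spec: SceneSpec


def default_objects(shape: tuple[int, int]) -> list[SceneObject]:
    """The standard plot layout, scaled to ``shape`` (back-to-front order).

    The film strip is deliberately larger than the plant so that weak
    vegetation-index coefficients (small alpha) leave it in the foreground
    and the largest-domain heuristic latches onto it — the documented
    failure mode the alpha sweep exposes.
    """
    h, w = shape

    def rect(r0, c0, r1, c1):
        return (int(r0 * h), int(c0 * w), int((r1 - r0) * h), int((c1 - c0) * w))

    def ellipse(rc, cc, ra, ca):
        return {"type": "ellipse", "center": (int(rc * h), int(cc * w)),
                "semi": (max(int(ra * h), 2), max(int(ca * w), 2))}

    return [
        SceneObject("soil", {"type": "full"}),
        SceneObject("film", {"type": "rect", "rect": rect(0.0, 0.02, 1.0, 0.32)}),
        SceneObject("straw", {"type": "rect", "rect": rect(0.85, 0.55, 0.95, 0.75)}),
        SceneObject("board", {"type": "rect", "rect": rect(0.04, 0.60, 0.16, 0.92)}),
        SceneObject("weed", ellipse(0.85, 0.40, 0.05, 0.035)),
        SceneObject("neighbor_plant", ellipse(0.30, 0.80, 0.10, 0.07)),
        SceneObject("plant", ellipse(0.55, 0.52, 0.26, 0.13)),
    ]


def _ellipse_mask(shape, center, semi) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    a, b = semi
    return ((rr - center[0]) / a) ** 2 + ((cc - center[1]) / b) ** 2 <= 1.0


def _majority_fixed_point(mask: np.ndarray, max_iter: int = 10) -> np.ndarray:
    """Iterate the 3x3 binary majority filter to a fixed point."""
    for _ in range(max_iter):
        new = ndimage.median_filter(mask.astype(np.uint8), size=3, mode="nearest")
        if np.array_equal(new, mask):
            break
        mask = new
    return mask.astype(bool)


def _spad_direction(profile: SensorProfile, model: SpadModel) -> np.ndarray:
    """Unit-response direction on model bands excluding 681/888 nm.

    d satisfies ``model_coefficients . d == 1`` and has zero entries at the
    vegetation-index bands, so shifting a spectrum by ``s * d`` changes the
    model prediction by exactly ``s`` and the MDVI not at all.
    """
    w = np.zeros(profile.n_bands)
    for wl, coef in model.terms.items():
        if wl not in (681.0, 888.0):
            w[profile.band_index(wl)] = coef
    return w / float(w @ w)


def generate_scene(spec: SceneSpec) -> SceneBundle:
    """Paint a scene back-to-front and derive all cubes and truths.

    Deterministic for a fixed seed: one generator drives signature jitter
    then pixel noise. Raises :class:`BadLayout` if the plant overlaps the
    board.
    """
    rng = np.random.default_rng(spec.seed)
    profile = spec.profile
    h, w = spec.shape
    n_bands = profile.n_bands
    objects = spec.objects if spec.objects is not None else default_objects(spec.shape)
    signatures = default_signatures(profile)

    refl = np.zeros((h, w, n_bands), dtype=float)
    object_masks: dict[str, np.ndarray] = {}
    board_rect: Rect | None = None
    board_boxes: list[Rect] = []

    for obj in objects:  # one jitter draw per object, in list order
        jitter = 1.0 + rng.normal(0.0, spec.signature_jitter_sd)
        geo = obj.geometry
        if obj.kind == "board":
            r0, c0, bh, bw = geo["rect"]
            board_rect = Rect(r0, c0, bh, bw)
            panel_w = bw // len(BOARD_LEVELS)
            for k, level in enumerate(BOARD_LEVELS):  # bright -> dark, unjittered
                pc0 = c0 + k * panel_w
                refl[r0 : r0 + bh, pc0 : pc0 + panel_w, :] = level
                board_boxes.append(Rect(r0 + 1, pc0 + 1, bh - 2, panel_w - 2))
            object_masks["board"] = np.zeros((h, w), bool)
            object_masks["board"][r0 : r0 + bh, c0 : c0 + len(BOARD_LEVELS) * panel_w] = True
            continue
        if geo["type"] == "full":
            mask = np.ones((h, w), bool)
        elif geo["type"] == "rect":
            r0, c0, rh, rw = geo["rect"]
            mask = np.zeros((h, w), bool)
            mask[r0 : r0 + rh, c0 : c0 + rw] = True
        elif geo["type"] == "ellipse":
            mask = _ellipse_mask((h, w), geo["center"], geo["semi"])
            mask = _majority_fixed_point(mask)
        else:
            raise ValueError(f"unknown geometry {geo['type']!r}")
        refl[mask] = signatures[obj.kind] * jitter
        object_masks[obj.kind] = mask

    if "plant" not in object_masks or not object_masks["plant"].any():
        raise BadLayout("scene must contain a non-empty plant object")
    plant = object_masks["plant"]
    if board_rect is not None and (plant & object_masks["board"]).any():
        raise BadLayout("plant overlaps the correction board")

    # Occlusion: later objects overwrite earlier ones; truth masks keep only
    # visible pixels.
    order = [o.kind for o in objects]
    for i, kind in enumerate(order):
        for later in order[i + 1 :]:
            if kind in object_masks and later in object_masks:
                object_masks[kind] &= ~object_masks[later]
    plant = object_masks["plant"]

    # Per-pixel SPAD field: left-to-right ramp, exactly invertible by the
    # published model, invisible to the vegetation index.
    model = load_published_model()
    direction = _spad_direction(profile, model)
    spad_truth = np.zeros((h, w), dtype=float)
    cols = np.where(plant.any(axis=0))[0]
    base_spectrum = refl[plant][0]
    s0 = float(model.intercept + sum(
        coef * base_spectrum[profile.band_index(wl)] for wl, coef in model.terms.items()
    ))
    if len(cols) > 1 and spec.spad_amplitude > 0:
        ramp = np.zeros(w)
        ramp[cols[0] : cols[-1] + 1] = np.linspace(-1.0, 1.0, cols[-1] - cols[0] + 1)
        offsets = spec.spad_amplitude * ramp[None, :]  # broadcast over rows
        spad_truth[plant] = s0 + np.broadcast_to(offsets, (h, w))[plant]
        refl[plant] = refl[plant] + (spad_truth[plant] - s0)[:, None] * direction[None, :]
    else:
        spad_truth[plant] = s0

    truth_cube = SpectralCube(
        data=refl.copy(), wavelengths=profile.wavelengths,
        value_kind="reflectance", bit_depth=profile.bit_depth,
    )

    measured = refl + rng.normal(0.0, spec.noise_sd, refl.shape) if spec.noise_sd > 0 else refl
    slope, offset = spec.gray_model
    gray = np.floor(np.asarray(slope) * measured + np.asarray(offset) + 0.5)
    gray = np.clip(gray, 0, 2 ** profile.bit_depth - 1).astype(np.uint16)
    gray_cube = SpectralCube(
        data=gray, wavelengths=profile.wavelengths,
        value_kind="grayscale", bit_depth=profile.bit_depth,
    )

    table_truth = {
        kind: refl[mask].mean(axis=0)
        for kind, mask in object_masks.items()
        if kind != "board" and mask.any()
    }
    return SceneBundle(
        cube_grayscale=gray_cube,
        cube_reflectance_truth=truth_cube,
        plant_mask_truth=BinaryMask(data=plant.astype(np.uint8), provenance="reference"),
        board_boxes=board_boxes,
        spad_truth=spad_truth,
        table_truth=table_truth,
        spec=spec,
    )


# -- spectra datasets -------------------------------------------------------

_DEFAULT_INFORMATIVE: tuple[float, ...] = (681.0, 888.0, 935.0)
_DEFAULT_WEIGHTS: tuple[float, ...] = (-50.0, 20.0, 20.0)
_DEFAULT_INTERCEPT = 12.6  # centers SPAD near the mid-30s for the base spectrum


def generate_spectra_dataset(
    n: int,
    seed: int,
    true_weights: np.ndarray | None = None,
    intercept: float | None = None,
    noise_sd: float = 1.0,
    informative_bands: tuple[float, ...] | None = None,
    structure: str = "lowrank",
    x_noise_sd: float = 0.004,
    profile: SensorProfile | None = None,
) -> SpectraTable:
    """Per-sample mean spectra with a known linear SPAD relation.

    ``structure="lowrank"`` draws smooth spectra from three latent factors
    (overall amplitude, red absorption depth, NIR tilt) plus small iid
    noise, emulating correlated canopy reflectance; ``"independent"`` makes
    every band an independent noisy level, the classic setting for testing
    variable selection against pure-noise bands.

    SPAD is exactly ``weights . R + intercept + N(0, noise_sd)`` on the
    delivered reflectance, with weights zero outside ``informative_bands``
    (defaults: 681/888/935 nm at -50/+20/+20, spanning roughly SPAD 17-53).
    """
    if profile is None:
        profile = reference_profile()
    wl = np.asarray(profile.wavelengths)
    p = profile.n_bands
    rng = np.random.default_rng(seed)

    if informative_bands is None:
        informative_bands = _DEFAULT_INFORMATIVE
        if true_weights is None:
            true_weights_full = np.zeros(p)
            for b, wgt in zip(_DEFAULT_INFORMATIVE, _DEFAULT_WEIGHTS):
                true_weights_full[profile.band_index(b)] = wgt
        else:
            true_weights_full = np.asarray(true_weights, dtype=float)
    else:
        informative_bands = tuple(float(b) for b in informative_bands)
        true_weights_full = np.zeros(p)
        if true_weights is None:
            # strong alternating weights on the designated bands
            for k, b in enumerate(informative_bands):
                true_weights_full[profile.band_index(b)] = 40.0 * (-1.0 if k % 2 else 1.0)
        else:
            tw = np.asarray(true_weights, dtype=float)
            if tw.shape == (len(informative_bands),):
                for b, wgt in zip(informative_bands, tw):
                    true_weights_full[profile.band_index(b)] = wgt
            else:
                true_weights_full = tw
    if intercept is None:
        intercept = _DEFAULT_INTERCEPT

    base = default_signatures(profile)["plant"]
    if structure == "lowrank":
        g_amp = base * 0.25
        g_red = np.interp(wl, [666, 681, 706, 732], [0.064, 0.08, 0.048, 0.0])
        g_red[wl > 732] = 0.0
        g_tilt = (wl - wl[0]) / (wl[-1] - wl[0]) * 0.08
        scores = rng.normal(size=(n, 3))
        X = base[None, :] + scores @ np.stack([g_amp, g_red, g_tilt])
        X += rng.normal(0.0, x_noise_sd, size=(n, p))
    elif structure == "independent":
        X = base[None, :] + rng.normal(0.0, 0.05, size=(n, p))
    else:
        raise ValueError(f"unknown structure {structure!r}")
    X = np.maximum(X, 0.0)  # reflectance floor; SPAD is computed afterwards

    y = X @ true_weights_full + intercept
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return SpectraTable(
        ids=[f"s{i:04d}" for i in range(n)],
        X=X,
        y=y,
        wavelengths=profile.wavelengths,
    )
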