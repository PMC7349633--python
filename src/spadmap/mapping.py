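"""Per-pixel SPAD prediction and pseudo-color distribution maps.

A :class:`SpadModel` is a sparse linear model on reflectance at selected
wavelengths, Y = sum_j c_j * R(lambda_j) + intercept. The shipped published
model (:func:`load_published_model`) carries ten terms on 681-935 nm with
intercept 43.828, as selected by UVE from field potato data. Applied per
pixel inside the plant mask it yields a SPAD raster, rendered as a
blue -> green -> yellow ramp (background and low values blue, high values
yellow).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .cube import BinaryMask, SpectralCube
from .errors import BadRange, EmptyMask, ModelCubeMismatch, ShapeMismatch

__all__ = [
    "SpadModel",
    "SpadMap",
    "load_published_model",
    "predict_pixel",
    "predict_map",
    "render_pseudocolor",
    "pseudocolor_lut",
]

# Ten-term UVE-PLS model on reflectance, SPAD units (published operating model).
_PUBLISHED_TERMS: tuple[tuple[float, float], ...] = (
    (681.0, -8.651),
    (816.0, 1.287),
    (827.0, -0.687),
    (837.0, 0.251),
    (849.0, 0.089),
    (859.0, -2.010),
    (869.0, 1.977),
    (888.0, -0.795),
    (910.0, 0.366),
    (935.0, 6.190),
)
_PUBLISHED_INTERCEPT = 43.828


@dataclass
class SpadModel:
    """Sparse linear SPAD model: terms (wavelength -> coefficient) + intercept."""

    terms: dict[float, float]
    intercept: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.terms = {float(w): float(c) for w, c in self.terms.items()}
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("model wavelengths must be unique")
        if not all(np.isfinite(list(self.terms.values()))) or not np.isfinite(self.intercept):
            raise ValueError("coefficients must be finite")

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return tuple(self.terms)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "terms": {f"{w:g}": c for w, c in self.terms.items()},
            "intercept": self.intercept,
            "provenance": self.provenance,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SpadModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        return cls(
            terms={float(w): float(c) for w, c in doc["terms"].items()},
            intercept=float(doc["intercept"]),
            provenance=doc.get("provenance", ""),
        )


@dataclass
class SpadMap:
    """H x W SPAD raster, zero outside the plant mask."""

    values: np.ndarray
    mask: BinaryMask
    mean_spad: float
    color_range: tuple[float, float] = (0.0, 60.0)

    def summary(self) -> dict:
        sel = self.mask.data.astype(bool)
        inside = self.values[sel]
        return {
            "mean_spad": float(self.mean_spad),
            "min": float(inside.min()),
            "max": float(inside.max()),
            "n_pixels": int(sel.sum()),
        }


def load_published_model() -> SpadModel:
    """The shipped ten-term UVE-PLS SPAD model (intercept 43.828)."""
    return SpadModel(
        terms=dict(_PUBLISHED_TERMS),
        intercept=_PUBLISHED_INTERCEPT,
        provenance="published ten-term UVE-PLS potato SPAD model",
    )


def predict_pixel(model: SpadModel, reflectance_by_wavelength: Mapping[float, float]) -> float:
    """Y = sum(c_j * R_j) + intercept for one pixel's spectrum."""
    total = model.intercept
    for wl, coef in model.terms.items():
        try:
            r = reflectance_by_wavelength[wl]
        except KeyError:
            raise ModelCubeMismatch(f"reflectance at {wl} nm missing") from None
        total += coef * float(r)
    return float(total)


def predict_map(cube: SpectralCube, mask: BinaryMask, model: SpadModel) -> SpadMap:
    """Apply the model to every masked pixel; zero outside the mask."""
    if mask.shape != cube.shape:
        raise ShapeMismatch(f"mask {mask.shape} vs cube {cube.shape}")
    sel = mask.data.astype(bool)
    if not sel.any():
        raise EmptyMask("mask has no foreground pixels")
    missing = [wl for wl in model.terms if wl not in cube.wavelengths]
    if missing:
        raise ModelCubeMismatch(f"cube lacks model bands: {missing}")
    values = np.zeros(cube.shape, dtype=float)
    acc = np.full(cube.shape, model.intercept, dtype=float)
    for wl, coef in model.terms.items():
        acc += coef * cube.band(wl).astype(float)
    values[sel] = acc[sel]
    return SpadMap(values=values, mask=mask, mean_spad=float(acc[sel].mean()))


def pseudocolor_lut() -> np.ndarray:
    """Fixed 256 x 3 uint8 blue -> green -> yellow lookup table.

    Channel-wise monotone along the ramp: R 0 -> 0 -> 255, G 0 -> 255 -> 255,
    B 255 -> 0 -> 0, so larger values are never less green/yellow.
    """
    anchors = np.array([[0, 0, 255], [0, 255, 0], [255, 255, 0]], dtype=float)
    positions = np.array([0.0, 0.5, 1.0])
    x = np.linspace(0.0, 1.0, 256)
    lut = np.stack(
        [np.interp(x, positions, anchors[:, ch]) for ch in range(3)], axis=1
    )
    return np.floor(lut + 0.5).astype(np.uint8)


def render_pseudocolor(
    spad_map: SpadMap, value_range: tuple[float, float] | None = None
) -> np.ndarray:
    """Render a SPAD map as an H x W x 3 uint8 image.

    Background pixels take the blue endpoint; masked values are clamped to
    ``value_range`` (default the map's ``color_range``) and mapped through
    the blue -> green -> yellow LUT.
    """
    low, high = value_range if value_range is not None else spad_map.color_range
    if low >= high:
        raise BadRange(f"need low < high, got ({low}, {high})")
    lut = pseudocolor_lut()
    clipped = np.clip(spad_map.values, low, high)
    idx = np.floor((clipped - low) / (high - low) * 255 + 0.5).astype(np.int64)
    rgb = lut[idx]
    rgb[spad_map.mask.data == 0] = lut[0]  # background is the blue endpoint
    return rgb
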