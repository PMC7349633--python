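"""Gray-level -> reflectance calibration against a multi-level standard board.

Field illumination drifts, so raw sensor gray levels are mapped to
reflectance through a per-wavelength affine law

    R_lambda = a_lambda * G_lambda + b_lambda

fitted by ordinary least squares on the four panels of a Spectralon-style
standard board with nominal reflectances 1.0, 0.75, 0.5 and 0 (high to low).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .cube import SpectralCube
from .errors import BadRegion, DegenerateCalibration, ModelCubeMismatch

__all__ = [
    "Rect",
    "BoardReading",
    "CalibrationModel",
    "BOARD_LEVELS",
    "extract_board_reading",
    "fit_calibration",
    "apply_calibration",
    "save_calibration",
    "load_calibration",
]

log = logging.getLogger(__name__)

#: Nominal reflectances of the 4-level standard board, brightest first.
BOARD_LEVELS: tuple[float, ...] = (1.0, 0.75, 0.5, 0.0)


class Rect(NamedTuple):
    """Axis-aligned pixel rectangle: top-left (row, col) plus height, width."""

    row: int
    col: int
    height: int
    width: int

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row, self.row + self.height), slice(self.col, self.col + self.width)


@dataclass
class BoardReading:
    """Mean gray level per band for each board panel.

    ``levels`` pairs each panel's nominal reflectance with its B-vector of
    mean gray values; ``region_boxes`` records the rectangles averaged over.
    """

    levels: list[tuple[float, np.ndarray]]
    region_boxes: list[Rect]


@dataclass
class CalibrationModel:
    """Per-wavelength affine gray->reflectance maps with fit quality.

    ``records`` maps wavelength (nm) to ``{"a": slope, "b": intercept,
    "r2": coefficient of determination}``.
    """

    records: dict[float, dict[str, float]]

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return tuple(self.records)

    def coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        """(slopes, intercepts) as B-vectors in record order."""
        a = np.array([r["a"] for r in self.records.values()])
        b = np.array([r["b"] for r in self.records.values()])
        return a, b


def extract_board_reading(
    cube: SpectralCube,
    region_boxes: Sequence[Rect | tuple[int, int, int, int]],
    nominal_reflectances: Sequence[float] = BOARD_LEVELS,
) -> BoardReading:
    """Average gray levels inside each panel rectangle, per band.

    ``region_boxes`` must match ``nominal_reflectances`` in order
    (brightest panel first by default).
    """
    if len(region_boxes) != len(nominal_reflectances):
        raise BadRegion(
            f"{len(region_boxes)} boxes for {len(nominal_reflectances)} board levels"
        )
    h, w = cube.shape
    levels: list[tuple[float, np.ndarray]] = []
    boxes: list[Rect] = []
    for nominal, box in zip(nominal_reflectances, region_boxes):
        rect = Rect(*box)
        if rect.height <= 0 or rect.width <= 0:
            raise BadRegion(f"zero-area or negative rectangle {rect}")
        if rect.row < 0 or rect.col < 0 or rect.row + rect.height > h or rect.col + rect.width > w:
            raise BadRegion(f"rectangle {rect} outside {h}x{w} image")
        rs, cs = rect.slices()
        means = cube.data[rs, cs, :].astype(float).mean(axis=(0, 1))
        levels.append((float(nominal), means))
        boxes.append(rect)
    return BoardReading(levels=levels, region_boxes=boxes)


def fit_calibration(reading: BoardReading, wavelengths: Sequence[float] | None = None) -> CalibrationModel:
    """Fit R = a*G + b per band by OLS over the board panels.

    ``wavelengths`` labels the bands (defaults to positional indices when
    the reading is detached from a cube — the pipeline always supplies the
    cube's wavelength list).
    """
    refl = np.array([lvl for lvl, _ in reading.levels], dtype=float)
    grays = np.stack([g for _, g in reading.levels], axis=0)  # L x B
    n_bands = grays.shape[1]
    if wavelengths is None:
        wavelengths = tuple(float(i) for i in range(n_bands))
    records: dict[float, dict[str, float]] = {}
    for j, wl in enumerate(wavelengths):
        g = grays[:, j]
        if np.ptp(g) == 0:
            raise DegenerateCalibration(
                f"all board levels share gray value {g[0]} in band {wl} nm"
            )
        a, b = np.polyfit(g, refl, 1)
        pred = a * g + b
        sst = float(np.sum((refl - refl.mean()) ** 2))
        sse = float(np.sum((refl - pred) ** 2))
        r2 = 1.0 - sse / sst if sst > 0 else 1.0
        records[float(wl)] = {"a": float(a), "b": float(b), "r2": float(np.clip(r2, 0.0, 1.0))}
    return CalibrationModel(records=records)


def apply_calibration(cube: SpectralCube, model: CalibrationModel) -> SpectralCube:
    """Map a grayscale cube to reflectance, band by band.

    Negative calibrated values are preserved (clipping would bias masked
    means) but counted and logged.
    """
    if model.wavelengths != cube.wavelengths:
        raise ModelCubeMismatch(
            f"model bands {model.wavelengths} != cube bands {cube.wavelengths}"
        )
    a, b = model.coefficients()
    refl = cube.data.astype(float) * a[None, None, :] + b[None, None, :]
    n_neg = int((refl < 0).sum())
    if n_neg:
        log.warning("calibration produced %d negative reflectance values (kept)", n_neg)
    return SpectralCube(
        data=refl,
        wavelengths=cube.wavelengths,
        value_kind="reflectance",
        bit_depth=cube.bit_depth,
    )


def save_calibration(model: CalibrationModel, path: str | Path) -> None:
    doc = {str(wl): rec for wl, rec in model.records.items()}
    Path(path).write_text(json.dumps(doc, indent=2))


def load_calibration(path: str | Path) -> CalibrationModel:
    doc = json.loads(Path(path).read_text())
    return CalibrationModel(records={float(wl): rec for wl, rec in doc.items()})
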