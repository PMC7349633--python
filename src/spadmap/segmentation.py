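"""Target-plant segmentation: MDVI + Otsu, then median filter + CDL.

Green canopy reflects strongly in the near infrared and absorbs in the red,
so the modified difference vegetation index

    MDVI(alpha) = I(888 nm) - alpha * I(681 nm)

amplifies the plant/background contrast; the modified coefficient alpha
tunes how aggressively bright backgrounds (mulch film, board panels) are
pushed negative. The preliminary mask is the Otsu foreground of the
min-max-rescaled MDVI image; precision segmentation median-filters it and
keeps only the largest connected domain (CDL), since weeds and neighboring
plants share the plant's spectrum but not its extent. Accuracy against a
reference mask is intersection-over-union as a percentage (MIoU).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .cube import BinaryMask, SpectralCube
from .errors import (
    BadWindow,
    ConstantImage,
    EmptyMask,
    EmptyUnion,
    ShapeMismatch,
)

__all__ = [
    "MdviImage",
    "RescaleRecord",
    "SegmentationResult",
    "AlphaSweepResult",
    "DEFAULT_ALPHAS",
    "compute_mdvi",
    "rescale_to_levels",
    "otsu_threshold",
    "median_filter_mask",
    "largest_component",
    "segment_plant",
    "miou",
    "alpha_sweep",
]

#: Modified coefficients of the standard sweep; 2.5 is the operating point.
DEFAULT_ALPHAS: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)


@dataclass
class MdviImage:
    """Real-valued MDVI raster plus the coefficient and bands that made it."""

    data: np.ndarray
    alpha: float
    source_wavelengths: tuple[float, float]  # (nir_nm, red_nm)


@dataclass
class RescaleRecord:
    """Affine map applied by :func:`rescale_to_levels` (for audit)."""

    scale: float
    offset: float
    constant_flag: bool


@dataclass
class SegmentationResult:
    """Preliminary and precision masks with the decisions that shaped them."""

    preliminary_mask: BinaryMask
    precision_mask: BinaryMask
    otsu_threshold: int
    component_count: int
    largest_component_area: int
    mdvi: MdviImage | None = None


@dataclass
class AlphaSweepResult:
    """Accuracy per modified coefficient; ``best_alpha`` is the arg-max."""

    table: pd.DataFrame  # columns: alpha, accuracy
    best_alpha: float


def compute_mdvi(
    cube: SpectralCube,
    alpha: float,
    nir_nm: float = 888,
    red_nm: float = 681,
) -> MdviImage:
    """Pixelwise NIR - alpha * red; real-valued, may be negative."""
    nir = cube.band(nir_nm).astype(float)
    red = cube.band(red_nm).astype(float)
    return MdviImage(
        data=nir - float(alpha) * red,
        alpha=float(alpha),
        source_wavelengths=(float(nir_nm), float(red_nm)),
    )


def rescale_to_levels(
    img: np.ndarray, levels: int = 256
) -> tuple[np.ndarray, RescaleRecord]:
    """Min-max rescale to integers 0..levels-1, rounding half up.

    A constant image maps to all zeros with ``constant_flag`` set (a flag,
    not an error: downstream Otsu raises on it).
    """
    img = np.asarray(img, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros(img.shape, dtype=np.int64), RescaleRecord(0.0, 0.0, True)
    scale = (levels - 1) / (hi - lo)
    scaled = (img - lo) * scale
    out = np.floor(scaled + 0.5).astype(np.int64)  # half-up, not banker's
    return out, RescaleRecord(scale=scale, offset=-lo * scale, constant_flag=False)


def otsu_threshold(img: np.ndarray, levels: int = 256) -> int:
    """Threshold maximizing between-class variance over t in 0..levels-2.

    Foreground is defined as ``value > t*``; ties between equally good
    thresholds go to the lowest t.
    """
    img = np.asarray(img)
    flat = img.ravel()
    if flat.min() < 0 or flat.max() > levels - 1:
        raise ValueError(f"values must lie in 0..{levels - 1}")
    hist = np.bincount(flat.astype(np.int64), minlength=levels).astype(float)
    if np.count_nonzero(hist) < 2:
        raise ConstantImage("Otsu needs at least two distinct gray levels")
    p = hist / hist.sum()
    omega = np.cumsum(p)                      # P(class0) for t = 0..levels-1
    mu = np.cumsum(p * np.arange(levels))     # first moment up to t
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b = np.nan_to_num(sigma_b[: levels - 1], nan=-1.0, posinf=-1.0)
    return int(np.argmax(sigma_b))  # argmax takes the first (lowest) maximizer


def median_filter_mask(mask: BinaryMask, window: int = 3) -> BinaryMask:
    """Binary median (majority) filter with edge replication at borders."""
    if window % 2 == 0 or window < 3:
        raise BadWindow(f"window must be an odd integer >= 3, got {window}")
    filtered = ndimage.median_filter(mask.data, size=window, mode="nearest")
    return BinaryMask(data=filtered.astype(np.uint8), provenance=mask.provenance)


def _label(mask_data: np.ndarray, connectivity: int) -> np.ndarray:
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    return measure.label(mask_data, connectivity=1 if connectivity == 4 else 2)


def largest_component(
    mask: BinaryMask, connectivity: int = 8
) -> tuple[BinaryMask, int, int]:
    """Keep one maximal-area connected domain; drop the rest as noise.

    Returns ``(mask, component_count, largest_area)``. Ties between
    equal-area components keep the one whose first pixel comes first in
    raster order (deterministic).
    """
    labels = _label(mask.data, connectivity)
    n_components = int(labels.max())
    if n_components == 0:
        raise EmptyMask("no foreground pixels")
    areas = np.bincount(labels.ravel())[1:]  # skip background label 0
    max_area = int(areas.max())
    winners = {int(lbl) for lbl in np.flatnonzero(areas == max_area) + 1}
    if len(winners) == 1:
        keep = winners.pop()
    else:
        flat = labels.ravel()
        keep = next(int(lbl) for lbl in flat if lbl in winners)
    out = BinaryMask(data=(labels == keep).astype(np.uint8), provenance="precision")
    return out, n_components, max_area


def segment_plant(
    cube: SpectralCube,
    alpha: float = 2.5,
    nir_nm: float = 888,
    red_nm: float = 681,
    window: int = 3,
    connectivity: int = 8,
    clip_negative: bool = True,
) -> SegmentationResult:
    """Full MDVI-OTSU-CDL chain on one cube.

    Pipeline: MDVI -> clip negatives to 0 -> rescale to 256 levels -> Otsu
    -> binarize (> t*) -> median filter -> largest connected domain.

    Negative MDVI carries no vegetation signal (it marks film, board
    panels, dark soil), and saturating it at zero — as uint8 image
    arithmetic does — keeps the histogram bimodal: without the clip,
    strongly negative film/board pixels stretch the min-max rescale and
    push soil toward the plant cluster, and Otsu then splits background
    classes instead of plant against background. ``clip_negative=False``
    restores the signed behavior.
    """
    mdvi = compute_mdvi(cube, alpha, nir_nm=nir_nm, red_nm=red_nm)
    index = np.maximum(mdvi.data, 0.0) if clip_negative else mdvi.data
    scaled, record = rescale_to_levels(index)
    if record.constant_flag:
        raise ConstantImage("MDVI image is constant; nothing to segment")
    t = otsu_threshold(scaled)
    preliminary = BinaryMask(data=(scaled > t).astype(np.uint8), provenance="preliminary")
    filtered = median_filter_mask(preliminary, window=window)
    precision, n_components, max_area = largest_component(filtered, connectivity=connectivity)
    return SegmentationResult(
        preliminary_mask=preliminary,
        precision_mask=precision,
        otsu_threshold=t,
        component_count=n_components,
        largest_component_area=max_area,
        mdvi=mdvi,
    )


def miou(reference: BinaryMask, segmented: BinaryMask) -> float:
    """Intersection-over-union of two masks, in percent."""
    if reference.shape != segmented.shape:
        raise ShapeMismatch(f"{reference.shape} vs {segmented.shape}")
    m1 = reference.data.astype(bool)
    m2 = segmented.data.astype(bool)
    union = int(np.count_nonzero(m1 | m2))
    if union == 0:
        raise EmptyUnion("both masks are empty; IoU undefined")
    inter = int(np.count_nonzero(m1 & m2))
    return 100.0 * inter / union


def alpha_sweep(
    cube: SpectralCube,
    reference: BinaryMask,
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
    **segment_kwargs,
) -> AlphaSweepResult:
    """Segmentation accuracy versus modified coefficient.

    Runs the full chain at each alpha, scores against ``reference`` with
    MIoU, and reports the arg-max coefficient (first on ties).
    """
    rows = []
    for alpha in alphas:
        result = segment_plant(cube, alpha=alpha, **segment_kwargs)
        rows.append({"alpha": float(alpha), "accuracy": miou(reference, result.precision_mask)})
    table = pd.DataFrame(rows)
    best = float(table.loc[table["accuracy"].idxmax(), "alpha"])
    return AlphaSweepResult(table=table, best_alpha=best)
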