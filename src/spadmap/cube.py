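"""Spectral cubes, binary masks, and their on-disk containers.

A :class:`SpectralCube` is an ``H x W x B`` raster with one wavelength per
band, either raw sensor gray levels or calibrated reflectance. Cubes travel
on disk as multi-page TIFF (one page per band, pages in profile wavelength
order) or as a directory of single-band images plus a JSON band manifest
``{"<wavelength_nm>": "<filename>", ...}``. Masks travel as single-band
PNG/PGM with 0/255 values, mapped to {0, 1} in memory.

Raw snapshot-mosaic frames (every pixel behind its own narrow-band filter,
tiled with period p) are decoded to cubes with :func:`mosaic_to_cube`; the
exact inverse :func:`cube_to_mosaic` re-interleaves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import BandNotFound, MissingBand, MosaicGeometry, ShapeMismatch
from .sensor import SensorProfile

__all__ = [
    "SpectralCube",
    "BinaryMask",
    "read_cube",
    "write_cube",
    "mosaic_to_cube",
    "cube_to_mosaic",
    "get_band",
    "read_mask",
    "write_mask",
]

MANIFEST_NAME = "bands.json"


@dataclass
class SpectralCube:
    """An H x W x B spectral raster with per-band wavelengths.

    ``value_kind`` is ``"grayscale"`` (raw sensor counts, bounded by
    ``2**bit_depth - 1``) or ``"reflectance"`` (calibrated, unitless).
    Band lookup is exact-match against the wavelength list.
    """

    data: np.ndarray
    wavelengths: tuple[float, ...]
    value_kind: str = "grayscale"
    bit_depth: int = 10

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = tuple(float(w) for w in self.wavelengths)
        if self.data.ndim != 3:
            raise ValueError("cube data must be H x W x B")
        if self.data.shape[2] != len(self.wavelengths):
            raise ValueError(
                f"{self.data.shape[2]} bands but {len(self.wavelengths)} wavelengths"
            )
        if self.value_kind not in ("grayscale", "reflectance"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of every band."""
        return self.data.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        try:
            return self.wavelengths.index(float(wavelength_nm))
        except ValueError:
            raise BandNotFound(
                f"{wavelength_nm} nm not in cube; available bands: "
                f"{list(self.wavelengths)}"
            ) from None

    def band(self, wavelength_nm: float) -> np.ndarray:
        """The H x W image at an exact-match wavelength."""
        return self.data[:, :, self.band_index(wavelength_nm)]


@dataclass
class BinaryMask:
    """An H x W plant/background raster over {0, 1} with a provenance tag.

    ``provenance`` records the pipeline stage that produced the mask
    (``preliminary`` | ``precision`` | ``reference`` | free text).
    """

    data: np.ndarray
    provenance: str = "reference"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 2:
            raise ValueError("mask must be 2-D")
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.data = data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def area(self) -> int:
        """Number of foreground pixels."""
        return int(self.data.sum())

    def require_same_shape(self, other: "BinaryMask | np.ndarray") -> None:
        shape = other.shape if isinstance(other, np.ndarray) else other.data.shape
        if shape[:2] != self.data.shape:
            raise ShapeMismatch(f"mask shape {self.data.shape} vs {shape[:2]}")


def get_band(cube: SpectralCube, wavelength_nm: float) -> np.ndarray:
    """The single H x W band at ``wavelength_nm`` (exact match)."""
    return cube.band(wavelength_nm)


def read_cube(path: str | Path, profile: SensorProfile) -> SpectralCube:
    """Read a cube from a multi-page TIFF or a band-manifest directory.

    Bands are returned in the profile's (ascending-wavelength) order
    regardless of manifest ordering; ``value_kind`` is ``grayscale``.
    """
    path = Path(path)
    if path.is_dir():
        bands = _read_band_directory(path, profile)
    else:
        pages = tifffile.imread(path)
        pages = np.asarray(pages)
        if pages.ndim == 2:
            pages = pages[None]
        if pages.shape[0] != profile.n_bands:
            raise MissingBand(
                f"{path} has {pages.shape[0]} pages, profile expects {profile.n_bands}"
            )
        bands = list(pages)
    shapes = {b.shape for b in bands}
    if len(shapes) != 1:
        raise ShapeMismatch(f"bands disagree on shape: {sorted(shapes)}")
    return SpectralCube(
        data=np.stack(bands, axis=-1),
        wavelengths=profile.wavelengths,
        value_kind="grayscale",
        bit_depth=profile.bit_depth,
    )


def _read_band_directory(path: Path, profile: SensorProfile) -> list[np.ndarray]:
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.exists():
        raise MissingBand(f"no {MANIFEST_NAME} manifest in {path}")
    manifest = {float(k): v for k, v in json.loads(manifest_path.read_text()).items()}
    unknown = set(manifest) - set(profile.wavelengths)
    if unknown:
        raise MissingBand(f"manifest wavelengths not in profile: {sorted(unknown)}")
    bands = []
    for wl in profile.wavelengths:
        if wl not in manifest:
            raise MissingBand(f"band {wl} nm missing from manifest in {path}")
        img = iio.imread(path / manifest[wl])
        if img.ndim == 3:  # collapse accidental RGB of a gray image
            img = img[:, :, 0]
        bands.append(np.asarray(img))
    return bands


def write_cube(path: str | Path, cube: SpectralCube) -> None:
    """Write a cube as a multi-page TIFF, one page per band, in band order.

    Lossless for integer grayscale cubes: ``read_cube(write_cube(c)) == c``.
    """
    pages = np.moveaxis(cube.data, -1, 0)
    tifffile.imwrite(Path(path), pages)


def mosaic_to_cube(raw: np.ndarray, profile: SensorProfile) -> SpectralCube:
    """Decode a raw mosaic frame into a cube.

    Pixel ``(i, j)`` of the band at tile position ``(r, c)`` is
    ``raw[i*p + r, j*p + c]`` with ``p = mosaic_period``; each band image
    has shape ``(H0/p, W0/p)``.
    """
    raw = np.asarray(raw)
    p = profile.mosaic_period
    if p * p != profile.n_bands:
        raise MosaicGeometry(f"mosaic_period**2 = {p * p} != {profile.n_bands} bands")
    if raw.ndim != 2 or raw.shape[0] % p or raw.shape[1] % p:
        raise MosaicGeometry(
            f"raw frame {raw.shape} is not a 2-D multiple of period {p}"
        )
    h, w = raw.shape[0] // p, raw.shape[1] // p
    data = np.empty((h, w, profile.n_bands), dtype=raw.dtype)
    for (r, c), b in profile.band_layout.items():
        data[:, :, b] = raw[r::p, c::p]
    return SpectralCube(
        data=data,
        wavelengths=profile.wavelengths,
        value_kind="grayscale",
        bit_depth=profile.bit_depth,
    )


def cube_to_mosaic(cube: SpectralCube, profile: SensorProfile) -> np.ndarray:
    """Re-interleave a cube into the raw mosaic frame (inverse of decode)."""
    p = profile.mosaic_period
    h, w = cube.shape
    raw = np.empty((h * p, w * p), dtype=cube.data.dtype)
    for (r, c), b in profile.band_layout.items():
        raw[r::p, c::p] = cube.data[:, :, b]
    return raw


def read_mask(path: str | Path, provenance: str = "reference") -> BinaryMask:
    """Read a 0/255 PNG/PGM mask; any nonzero pixel becomes foreground."""
    img = iio.imread(Path(path))
    if img.ndim == 3:
        img = img[:, :, 0]
    return BinaryMask(data=(np.asarray(img) > 0).astype(np.uint8), provenance=provenance)


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    """Write a mask as 0/255 single-band image (format from extension)."""
    iio.imwrite(Path(path), (mask.data * 255).astype(np.uint8))
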