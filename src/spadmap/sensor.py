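"""Sensor profiles for snapshot-mosaic multispectral cameras.

A :class:`SensorProfile` describes the band set of a camera whose focal
plane carries a p x p mosaic of narrow-band filters (one filter per pixel,
so a raw frame interleaves all bands). The reference profile models a
25-band (5 x 5 mosaic) VNIR sensor with band centers between 666 and
945 nm, 10-bit gray levels, and an FWHM that widens toward longer
wavelengths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "SensorProfile",
    "REFERENCE_WAVELENGTHS",
    "REFERENCE_FWHM",
    "reference_profile",
    "load_profile",
    "save_profile",
]

# Band centers (nm) of the reference 25-band VNIR mosaic sensor, ascending.
# 887 and 888 nm are two distinct physical filters and both are addressable.
REFERENCE_WAVELENGTHS: tuple[float, ...] = (
    666, 681, 706, 720, 732, 746, 759,
    772, 784, 796, 816, 827,
    837, 849, 859, 869, 887,
    888, 902, 910, 920, 926,
    935, 940, 945,
)

# FWHM (nm) per band; constant within each filter-technology group.
REFERENCE_FWHM: tuple[float, ...] = (
    (3.35,) * 7 + (4.69,) * 5 + (6.04,) * 5 + (7.39,) * 5 + (12.10,) * 3
)


@dataclass(frozen=True)
class SensorProfile:
    """Band geometry of a snapshot-mosaic multispectral sensor.

    Parameters
    ----------
    wavelengths
        Band centers in nm, strictly increasing.
    fwhm
        Full width at half maximum per band, nm; same length as
        ``wavelengths``.
    mosaic_period
        Edge length p of the p x p filter tile (``p**2`` must equal the
        band count when mosaic decoding is used).
    band_layout
        Mapping ``(row_in_tile, col_in_tile) -> band index``; a bijection
        onto ``0..B-1``. Defaults to row-major order over the tile.
    bit_depth
        ADC resolution of the sensor in bits.
    """

    wavelengths: tuple[float, ...]
    fwhm: tuple[float, ...]
    mosaic_period: int = 5
    band_layout: dict[tuple[int, int], int] = field(default_factory=dict)
    bit_depth: int = 10

    def __post_init__(self) -> None:
        wl = tuple(float(w) for w in self.wavelengths)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "fwhm", tuple(float(f) for f in self.fwhm))
        if len(self.fwhm) != len(wl):
            raise ValueError("fwhm and wavelengths must have equal length")
        if any(b >= a for a, b in zip(wl[1:], wl)):
            raise ValueError("wavelengths must be strictly increasing")
        if not self.band_layout:
            p = self.mosaic_period
            layout = {(r, c): r * p + c for r in range(p) for c in range(p)}
            object.__setattr__(self, "band_layout", layout)
        vals = sorted(self.band_layout.values())
        if vals != list(range(len(self.band_layout))):
            raise ValueError("band_layout must be a bijection onto 0..B-1")

    @property
    def n_bands(self) -> int:
        return len(self.wavelengths)

    def band_index(self, wavelength_nm: float) -> int:
        """Index of an exact-match wavelength; raises ValueError if absent."""
        try:
            return self.wavelengths.index(float(wavelength_nm))
        except ValueError:
            raise ValueError(
                f"{wavelength_nm} nm not in profile; available: {self.wavelengths}"
            ) from None


def reference_profile() -> SensorProfile:
    """The 25-band 5x5-mosaic reference sensor profile."""
    return SensorProfile(
        wavelengths=REFERENCE_WAVELENGTHS,
        fwhm=REFERENCE_FWHM,
        mosaic_period=5,
        bit_depth=10,
    )


def _profile_to_dict(profile: SensorProfile) -> dict:
    return {
        "wavelengths": list(profile.wavelengths),
        "fwhm": list(profile.fwhm),
        "mosaic_period": profile.mosaic_period,
        "bit_depth": profile.bit_depth,
        "band_layout": {
            f"{r},{c}": b for (r, c), b in sorted(profile.band_layout.items())
        },
    }


def _profile_from_dict(doc: dict) -> SensorProfile:
    layout = {}
    for key, b in (doc.get("band_layout") or {}).items():
        r, c = (int(x) for x in key.split(","))
        layout[(r, c)] = int(b)
    return SensorProfile(
        wavelengths=tuple(doc["wavelengths"]),
        fwhm=tuple(doc["fwhm"]),
        mosaic_period=int(doc.get("mosaic_period", 5)),
        band_layout=layout,
        bit_depth=int(doc.get("bit_depth", 10)),
    )


def save_profile(profile: SensorProfile, path: str | Path) -> None:
    """Write a profile as JSON (``.json``) or YAML (anything else)."""
    path = Path(path)
    doc = _profile_to_dict(profile)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def load_profile(path: str | Path) -> SensorProfile:
    """Read a profile written by :func:`save_profile`."""
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return _profile_from_dict(doc)
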