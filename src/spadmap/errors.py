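"""Exception hierarchy.

Two broad families matter to callers: :class:`InputError` (bad files,
geometry, or arguments — CLI exit code 2) and :class:`DegenerateDataError`
(inputs that are structurally fine but carry no usable signal — exit code 3).
"""


class SpadmapError(Exception):
    """Base class for all spadmap errors."""


class InputError(SpadmapError):
    """Invalid input: missing files/bands, bad geometry, bad arguments."""


class DegenerateDataError(SpadmapError):
    """Structurally valid input with no exploitable variation."""


# -- spectral I/O -----------------------------------------------------------

class MissingBand(InputError):
    """A cube container does not provide every band of the sensor profile."""


class MosaicGeometry(InputError):
    """Raw mosaic frame dimensions are not multiples of the tile period."""


class BandNotFound(InputError):
    """Requested wavelength is not an exact member of the cube's band list."""


# -- calibration ------------------------------------------------------------

class BadRegion(InputError):
    """Board region rectangle is empty or falls outside the image."""


class DegenerateCalibration(DegenerateDataError):
    """All board gray levels coincide in a band; no line can be fitted."""


class ModelCubeMismatch(InputError):
    """Model wavelengths and cube wavelengths do not agree."""


# -- segmentation -----------------------------------------------------------

class ConstantImage(DegenerateDataError):
    """Otsu thresholding requires at least two distinct gray levels."""


class BadWindow(InputError):
    """Median filter window must be an odd integer >= 3."""


class EmptyMask(InputError):
    """Operation requires at least one foreground pixel."""


class ShapeMismatch(InputError):
    """Two rasters that must align have different shapes."""


class EmptyUnion(DegenerateDataError):
    """MIoU of two empty masks is undefined."""


# -- chemometrics -----------------------------------------------------------

class TooFewSamples(InputError):
    """Not enough samples for the requested split or fit."""


class BadComponents(InputError):
    """PLS component count outside [1, min(n - 1, p)]."""


class DegenerateTarget(DegenerateDataError):
    """Response vector has zero variance."""


class DegenerateMetric(DegenerateDataError):
    """A metric (e.g. RPD with RMSE = 0) is undefined for these inputs."""


# -- mapping / scenes -------------------------------------------------------

class BadRange(InputError):
    """Rendering range must satisfy low < high."""


class BadLayout(InputError):
    """Synthetic scene objects overlap in a forbidden way."""
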