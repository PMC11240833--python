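"""Exception hierarchy for the dxafemur toolkit."""


class DxaError(Exception):
    """Base class for all toolkit errors."""


class MissingFileError(DxaError, FileNotFoundError):
    """A required file or bundle component does not exist."""


class MultiChannelImageError(DxaError, ValueError):
    """Image has more than one channel; the toolkit is grayscale-only."""


class UnsupportedBitDepthError(DxaError, ValueError):
    """Image bit depth is not 8- or 16-bit integer grayscale."""


class ImageRangeError(DxaError, ValueError):
    """Pixel values do not fit the requested output bit depth."""


class ShapeMismatchError(DxaError, ValueError):
    """Two images or masks that must align have different shapes."""


class InvalidMetaError(DxaError, ValueError):
    """Scan metadata is missing fields or violates positivity constraints."""


class GeometryError(DxaError, ValueError):
    """Phantom geometry does not fit inside the image or the body outline."""


class DegenerateScanError(DxaError, ValueError):
    """Scan statistics make a calibration quantity undefined (e.g. mean
    count equal to the incident count, so its log-attenuation is zero)."""


class SingularCalibrationError(DxaError, ZeroDivisionError):
    """u_l - u_h * Rst vanished; the bone-density image is undefined."""


class DegenerateRoiError(DxaError, ValueError):
    """An ROI statistic needed for a quality metric is degenerate
    (zero standard deviation, non-positive mean, equal means)."""
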