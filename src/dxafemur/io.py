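"""Grayscale image I/O and the on-disk scan-bundle format.

A dual-energy scan is persisted as a directory::

    bundle/
      he.png      16-bit grayscale, detector counts x count_scale
      le.png      16-bit grayscale, detector counts x count_scale
      meta.json   acquisition constants (he0, le0, u_l, u_h,
                  pixel_size_mm, count_scale)

Counts are stored as integers scaled by ``count_scale`` so that simulated
sub-integer counts survive a save/load round trip to quantization
precision; scans whose counts are already 16-bit integers round-trip
bit-exactly at ``count_scale = 1``.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import (
    ImageRangeError,
    InvalidMetaError,
    MissingFileError,
    MultiChannelImageError,
    ShapeMismatchError,
    UnsupportedBitDepthError,
)

__all__ = ["DualEnergyScan", "read_image", "write_image", "save_scan", "load_scan"]

_MAX = {8: 255, 16: 65535}


@dataclass
class DualEnergyScan:
    """Paired high-energy / low-energy detector-count images.

    Attributes
    ----------
    he, le : ndarray
        Detector counts per pixel at high and low energy; strictly positive.
    he0, le0 : float
        Incident (unattenuated) counts of the two beams.
    u_l, u_h : float
        Per-energy calibration constants of the low/high-energy beams
        (mass attenuation of bone, cm^2/g, in the phantom's convention).
    pixel_size : float
        Pixel side length in mm.
    """

    he: np.ndarray
    le: np.ndarray
    he0: float
    le0: float
    u_l: float
    u_h: float
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.he = np.asarray(self.he, dtype=float)
        self.le = np.asarray(self.le, dtype=float)
        if self.he.ndim != 2 or self.le.ndim != 2:
            raise InvalidMetaError("HE and LE images must be 2D")
        if self.he.shape != self.le.shape:
            raise ShapeMismatchError(
                f"HE shape {self.he.shape} != LE shape {self.le.shape}"
            )
        for name in ("he0", "le0", "u_l", "u_h", "pixel_size"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidMetaError(f"{name} must be strictly positive, got {v}")
        if not (np.isfinite(self.he).all() and np.isfinite(self.le).all()):
            raise InvalidMetaError("counts must be finite")
        if (self.he <= 0).any() or (self.le <= 0).any():
            raise InvalidMetaError("all counts must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.he.shape


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8- or 16-bit single-channel PNG/TIFF as a float array.

    Integer codes are preserved exactly.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such image: {path}")
    with Image.open(path) as im:
        if im.mode in ("RGB", "RGBA", "CMYK", "YCbCr", "LA"):
            raise MultiChannelImageError(
                f"{path}: expected single-channel image, got mode {im.mode}"
            )
        if im.mode not in ("L", "I", "I;16", "I;16B", "I;16L"):
            raise UnsupportedBitDepthError(
                f"{path}: unsupported mode {im.mode}; need 8/16-bit grayscale"
            )
        arr = np.asarray(im, dtype=np.int64)
    if arr.ndim != 2:
        raise MultiChannelImageError(f"{path}: image is not 2D")
    if arr.max(initial=0) > _MAX[16] or arr.min(initial=0) < 0:
        raise UnsupportedBitDepthError(f"{path}: values exceed 16-bit range")
    return arr.astype(float)


def write_image(img: np.ndarray, path: str | Path, bit_depth: int = 16) -> None:
    """Write a 2D array as an 8- or 16-bit grayscale PNG/TIFF.

    Values are rounded half-to-even; after rounding they must lie in the
    representable range of ``bit_depth`` or :class:`ImageRangeError` is raised.
    """
    if bit_depth not in _MAX:
        raise UnsupportedBitDepthError(f"bit_depth must be 8 or 16, got {bit_depth}")
    arr = np.rint(np.asarray(img, dtype=float))
    if not np.isfinite(arr).all():
        raise ImageRangeError("non-finite pixel values")
    if arr.min() < 0 or arr.max() > _MAX[bit_depth]:
        raise ImageRangeError(
            f"values [{arr.min()}, {arr.max()}] outside 0..{_MAX[bit_depth]}"
        )
    if bit_depth == 8:
        im = Image.fromarray(arr.astype(np.uint8), mode="L")
    else:
        im = Image.fromarray(arr.astype(np.uint16))
    im.save(Path(path))


def _auto_count_scale(scan: DualEnergyScan) -> float:
    top = max(scan.he.max(), scan.le.max())
    integral = np.array_equal(scan.he, np.rint(scan.he)) and np.array_equal(
        scan.le, np.rint(scan.le)
    )
    if integral and top <= _MAX[16]:
        return 1.0
    return _MAX[16] / math.ceil(top + 1)


def save_scan(scan: DualEnergyScan, bundle_dir: str | Path, count_scale: float | None = None) -> Path:
    """Persist a scan as a ``{he.png, le.png, meta.json}`` bundle directory."""
    d = Path(bundle_dir)
    d.mkdir(parents=True, exist_ok=True)
    if count_scale is None:
        count_scale = _auto_count_scale(scan)
    if not count_scale > 0:
        raise InvalidMetaError("count_scale must be positive")
    write_image(scan.he * count_scale, d / "he.png", 16)
    write_image(scan.le * count_scale, d / "le.png", 16)
    meta = {
        "he0": scan.he0,
        "le0": scan.le0,
        "u_l": scan.u_l,
        "u_h": scan.u_h,
        "pixel_size_mm": scan.pixel_size,
        "count_scale": count_scale,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))
    return d


def load_scan(bundle_dir: str | Path) -> DualEnergyScan:
    """Load and validate a scan bundle written by :func:`save_scan`."""
    d = Path(bundle_dir)
    for name in ("he.png", "le.png", "meta.json"):
        if not (d / name).exists():
            raise MissingFileError(f"bundle {d} is missing {name}")
    try:
        meta = json.loads((d / "meta.json").read_text())
    except json.JSONDecodeError as e:
        raise InvalidMetaError(f"{d}/meta.json is not valid JSON: {e}") from e
    required = {"he0", "le0", "u_l", "u_h", "pixel_size_mm", "count_scale"}
    missing = required - meta.keys()
    if missing:
        raise InvalidMetaError(f"meta.json missing fields: {sorted(missing)}")
    scale = meta["count_scale"]
    if not (isinstance(scale, (int, float)) and scale > 0):
        raise InvalidMetaError(f"count_scale must be positive, got {scale}")
    he = read_image(d / "he.png") / scale
    le = read_image(d / "le.png") / scale
    # DualEnergyScan.__post_init__ enforces shape equality and positivity
    return DualEnergyScan(
        he=he,
        le=le,
        he0=meta["he0"],
        le0=meta["le0"],
        u_l=meta["u_l"],
        u_h=meta["u_h"],
        pixel_size=meta["pixel_size_mm"],
    )
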