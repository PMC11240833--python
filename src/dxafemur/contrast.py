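"""High-contrast display images derived from a dual-energy scan.

Three display images are generated from the HE/LE count pair:

``ibd``
    Bone-density image.  With ``Rst`` the beam-calibration ratio (below),

        IBD = Rst * (ln(HEi/HE0) - ln(LEi/LE0)) / (u_l - u_h * Rst)

    Because bone attenuates the low-energy beam much more strongly than
    soft tissue does, IBD is brighter over bone than over soft tissue and
    is affine in the bone areal density when the soft-tissue thickness is
    uniform.  It doubles as the per-pixel BMD map.

``ilr``
    Log-ratio image, ILR = (T - ln(HEi+LEi)/ln(u_l+u_h)) ** (B+C).
    Negative bases (possible for extreme counts) are clipped to 0 before
    the non-integer power.

``ci``
    Collage image.  With r = ln(LEi/HEi), mu = mean(r), delta = std(r):

        CI = [(ln(HEi/LEi) - ln(LEi/HEi)) / (1 + exp(-delta*(r - mu)))] * (B+C)
             - ln(LEi)

    The sigmoid modulates the symmetric log-contrast term by how far a
    pixel's energy ratio sits from the image mean; a constant-ratio image
    is legal (sigmoid = 1/2).

All logarithms are natural.  ``Rst`` itself is a whole-image scalar:

    Rst = ln(LE0 / mean(LEi)) / ln(HE0 / mean(HEi))
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DegenerateScanError, SingularCalibrationError
from .io import DualEnergyScan

__all__ = [
    "ContrastParams",
    "DisplayImage",
    "compute_rst",
    "make_ibd",
    "make_ilr",
    "make_ci",
    "normalize_to_8bit",
]


@dataclass(frozen=True)
class ContrastParams:
    """Constants of the ILR/CI generators.

    T is a fixed offset (must exceed 1); B and C are brightness and
    contrast enhancement constants entering only through their sum.
    """

    T: float = 2.0
    B: float = 1.0
    C: float = 0.5

    def __post_init__(self) -> None:
        if not self.T > 1:
            raise ValueError(f"T must exceed 1, got {self.T}")
        if not self.B + self.C > 0:
            raise ValueError(f"B + C must be positive, got {self.B + self.C}")


@dataclass
class DisplayImage:
    """A derived float image plus the recipe that produced it."""

    pixels: np.ndarray
    kind: str  # "ibd" | "ilr" | "ci"
    params: Optional[ContrastParams] = None
    rst: Optional[float] = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def compute_rst(scan: DualEnergyScan) -> float:
    """Beam-calibration ratio of mean log-attenuations, Eq. above."""
    num = np.log(scan.le0 / scan.le.mean())
    den = np.log(scan.he0 / scan.he.mean())
    if den == 0.0 or num == 0.0:
        raise DegenerateScanError(
            "mean count equals incident count; Rst undefined"
        )
    return float(num / den)


def make_ibd(scan: DualEnergyScan) -> DisplayImage:
    """Bone-density display image (brighter bone, darker soft tissue)."""
    rst = compute_rst(scan)
    denom = scan.u_l - scan.u_h * rst
    if denom == 0.0:
        raise SingularCalibrationError(
            f"u_l - u_h*Rst = 0 (u_l={scan.u_l}, u_h={scan.u_h}, Rst={rst})"
        )
    pix = rst * (np.log(scan.he / scan.he0) - np.log(scan.le / scan.le0)) / denom
    return DisplayImage(pixels=pix, kind="ibd", rst=rst)


def make_ilr(scan: DualEnergyScan, params: ContrastParams | None = None) -> DisplayImage:
    """Log-ratio display image."""
    p = params or ContrastParams()
    if scan.u_l + scan.u_h == 1.0:
        raise DegenerateScanError("u_l + u_h = 1 makes ln(u_l+u_h) zero")
    base = p.T - np.log(scan.he + scan.le) / np.log(scan.u_l + scan.u_h)
    # non-integer powers of negative reals are undefined; clip keeps the
    # map total and monotone
    pix = np.clip(base, 0.0, None) ** (p.B + p.C)
    return DisplayImage(pixels=pix, kind="ilr", params=p)


def make_ci(scan: DualEnergyScan, params: ContrastParams | None = None) -> DisplayImage:
    """Collage display image (highest contrast of the three)."""
    p = params or ContrastParams()
    r = np.log(scan.le / scan.he)
    mu = r.mean()
    delta = r.std()  # population std; 0 for a constant ratio field -> sigmoid 1/2
    sigmoid = 1.0 / (1.0 + np.exp(-delta * (r - mu)))
    pix = (-2.0 * r / sigmoid) * (p.B + p.C) - np.log(scan.le)
    return DisplayImage(pixels=pix, kind="ci", params=p)


def normalize_to_8bit(img: DisplayImage) -> DisplayImage:
    """Linear min-max rescale to [0, 255], rounded half-to-even.

    A constant image has no contrast to stretch and maps to all zeros.
    """
    pix = img.pixels
    lo, hi = pix.min(), pix.max()
    if hi == lo:
        out = np.zeros_like(pix)
    else:
        out = np.rint((pix - lo) * (255.0 / (hi - lo)))
    return DisplayImage(pixels=out, kind=img.kind, params=img.params, rst=img.rst)
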