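"""Denoising filters for DXA count and display images.

Three filter families are provided, each with the configuration used for
the femur pipeline:

* non-local means (``nlmf``): 21x21 search window, 7x7 patches, strength
  h = 10; classic patch-similarity weights w = exp(-d^2/h^2) where d^2 is
  the mean squared difference between reflect-padded patches;
* Gaussian (``gf``): truncated, renormalized kernel, sigma = 1.5,
  5x5 kernel;
* wavelet shrinkage (``cwt-st`` / ``cwt-ht``): db2, 3 decomposition
  levels, soft or hard thresholding of the detail coefficients with the
  universal (VisuShrink) threshold T = sigma_hat * sqrt(2 ln n),
  sigma_hat = median(|finest diagonal details|) / 0.6745.

All filters are deterministic, shape-preserving, and use the same
edge-inclusive (half-sample symmetric) reflection at the boundary.  ``denoise_scan`` applies a filter either to the HE
and LE count images before display generation (stage ``pre``, the
default) or to a display image (stage ``post``).
"""
from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pywt
from scipy import ndimage

from .contrast import ContrastParams, DisplayImage, make_ci
from .io import DualEnergyScan

__all__ = [
    "NLMParams",
    "GaussianParams",
    "WaveletParams",
    "hard_threshold",
    "soft_threshold",
    "gaussian_denoise",
    "nlm_denoise",
    "wavelet_denoise",
    "denoise_scan",
    "METHODS",
]

METHODS = ("none", "nlmf", "gf", "cwt-st", "cwt-ht")


@dataclass(frozen=True)
class NLMParams:
    search_window: int = 21
    patch: int = 7
    h: float = 10.0

    def __post_init__(self) -> None:
        if self.search_window % 2 == 0 or self.patch % 2 == 0:
            raise ValueError("search_window and patch must be odd")
        if self.patch > self.search_window:
            raise ValueError("patch must not exceed search_window")
        if not self.h > 0:
            raise ValueError("filtering strength h must be positive")


@dataclass(frozen=True)
class GaussianParams:
    sigma: float = 1.5
    kernel: int = 5

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if self.kernel % 2 == 0 or self.kernel < 3:
            raise ValueError("kernel must be odd and >= 3")


@dataclass(frozen=True)
class WaveletParams:
    wavelet: str = "db2"
    level: int = 3
    mode: str = "soft"  # "soft" | "hard"
    threshold_rule: str = "universal"  # "universal" | "fixed"
    threshold: float = 0.0  # used when threshold_rule == "fixed"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("level must be >= 1")
        if self.mode not in ("soft", "hard"):
            raise ValueError(f"mode must be 'soft' or 'hard', got {self.mode!r}")
        if self.threshold_rule not in ("universal", "fixed"):
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")
        if self.threshold_rule == "fixed" and self.threshold < 0:
            raise ValueError("fixed threshold must be >= 0")


def hard_threshold(x, T: float):
    """Keep-or-kill shrinkage: y = x where |x| > T, else 0."""
    if T < 0:
        raise ValueError("threshold must be >= 0")
    x = np.asarray(x, dtype=float)
    return np.where(np.abs(x) > T, x, 0.0)


def soft_threshold(x, T: float):
    """Shrink-toward-zero: y = sign(x) * max(|x| - T, 0)."""
    if T < 0:
        raise ValueError("threshold must be >= 0")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - T, 0.0)


def _gaussian_kernel(sigma: float, size: int) -> np.ndarray:
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    return k / k.sum()


def gaussian_denoise(img: np.ndarray, params: GaussianParams | None = None) -> np.ndarray:
    """Convolution with a truncated, renormalized Gaussian kernel."""
    p = params or GaussianParams()
    img = np.asarray(img, dtype=float)
    if p.kernel > min(img.shape):
        raise ValueError(f"kernel {p.kernel} larger than image {img.shape}")
    return ndimage.convolve(img, _gaussian_kernel(p.sigma, p.kernel), mode="reflect")


def nlm_denoise(img: np.ndarray, params: NLMParams | None = None) -> np.ndarray:
    """Non-local means with classic exponential patch-similarity weights.

    Implemented by iterating over the (2s+1)^2 search offsets; for each
    offset the per-pixel mean squared patch difference is a box filter of
    the shifted squared-difference image, so the whole filter is O(S^2)
    box filters rather than O(N * S^2 * P^2) loops.  Equivalent, by
    construction, to the literal definition on a reflect-padded image.
    """
    p = params or NLMParams()
    img = np.asarray(img, dtype=float)
    if min(img.shape) < p.patch:
        raise ValueError(f"image {img.shape} smaller than patch {p.patch}")
    H, W = img.shape
    s, f = p.search_window // 2, p.patch // 2
    pad = np.pad(img, s + f, mode="symmetric")
    num = np.zeros((H, W))
    den = np.zeros((H, W))
    h2 = p.h**2
    for di in range(-s, s + 1):
        for dj in range(-s, s + 1):
            # squared difference between the patch neighborhoods of each
            # core pixel and its offset partner, defined out to +-f
            a = pad[s + di : s + di + H + 2 * f, s + dj : s + dj + W + 2 * f]
            b = pad[s : s + H + 2 * f, s : s + W + 2 * f]
            sq = (a - b) ** 2
            d2 = ndimage.uniform_filter(sq, size=p.patch)[f : f + H, f : f + W]
            # uniform_filter normalizes by patch area already; guard tiny
            # negative rounding
            w = np.exp(-np.maximum(d2, 0.0) / h2)
            v = pad[s + f + di : s + f + di + H, s + f + dj : s + f + dj + W]
            num += w * v
            den += w
    return num / den


def wavelet_denoise(img: np.ndarray, params: WaveletParams | None = None) -> np.ndarray:
    """Multilevel DWT, detail-coefficient shrinkage, inverse transform.

    The approximation band is left untouched.  With the universal rule
    the threshold is estimated from the finest diagonal detail band; a
    constant image has sigma_hat = 0 and reconstructs (near-)exactly.
    """
    p = params or WaveletParams()
    img = np.asarray(img, dtype=float)
    wav = pywt.Wavelet(p.wavelet)
    max_level = pywt.dwtn_max_level(img.shape, wav)
    if p.level > max_level:
        raise ValueError(
            f"level {p.level} too deep for image {img.shape} with {p.wavelet} "
            f"(max {max_level})"
        )
    coeffs = pywt.wavedec2(img, wav, level=p.level, mode="symmetric")
    if p.threshold_rule == "universal":
        finest_diag = coeffs[-1][2]
        sigma_hat = np.median(np.abs(finest_diag)) / 0.6745
        T = sigma_hat * np.sqrt(2.0 * np.log(img.size))
    else:
        T = p.threshold
    shrink = soft_threshold if p.mode == "soft" else hard_threshold
    out = [coeffs[0]]
    for detail in coeffs[1:]:
        out.append(tuple(shrink(d, T) for d in detail))
    rec = pywt.waverec2(out, wav, mode="symmetric")
    return rec[: img.shape[0], : img.shape[1]]


def _apply(img: np.ndarray, method: str, nlm=None, gauss=None, wavelet=None) -> np.ndarray:
    if method == "none":
        return np.asarray(img, dtype=float)
    if method == "nlmf":
        return nlm_denoise(img, nlm)
    if method == "gf":
        return gaussian_denoise(img, gauss)
    if method in ("cwt-st", "cwt-ht"):
        p = wavelet or WaveletParams()
        p = _dc_replace(p, mode="soft" if method == "cwt-st" else "hard")
        return wavelet_denoise(img, p)
    raise ValueError(f"unknown denoising method {method!r}; choose from {METHODS}")


def denoise_scan(
    scan: DualEnergyScan,
    method: str,
    stage: str = "pre",
    display: DisplayImage | None = None,
    nlm: NLMParams | None = None,
    gauss: GaussianParams | None = None,
    wavelet: WaveletParams | None = None,
):
    """Apply a named filter to a scan (stage ``pre``) or display image.

    stage ``pre``
        Filters HE and LE count images independently and returns a new
        :class:`DualEnergyScan` (counts re-clamped to >= 1 so logs stay
        finite).
    stage ``post``
        Filters the pixels of ``display`` (a collage image generated
        with default parameters if not supplied) and returns a new
        :class:`DisplayImage`.
    """
    if method not in METHODS:
        raise ValueError(f"unknown denoising method {method!r}; choose from {METHODS}")
    if stage == "pre":
        if method == "none":
            return scan
        he = np.maximum(_apply(scan.he, method, nlm, gauss, wavelet), 1.0)
        le = np.maximum(_apply(scan.le, method, nlm, gauss, wavelet), 1.0)
        return DualEnergyScan(
            he=he, le=le, he0=scan.he0, le0=scan.le0,
            u_l=scan.u_l, u_h=scan.u_h, pixel_size=scan.pixel_size,
        )
    if stage == "post":
        if display is None:
            display = make_ci(scan, ContrastParams())
        pix = _apply(display.pixels, method, nlm, gauss, wavelet)
        return DisplayImage(
            pixels=pix, kind=display.kind, params=display.params, rst=display.rst
        )
    raise ValueError(f"stage must be 'pre' or 'post', got {stage!r}")
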