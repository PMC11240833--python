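"""Synthetic dual-energy femur phantom.

The phantom stands in for clinical hip DXA scans: a proximal femur built
from 2D parametric primitives (head disk, neck band, shaft rectangle,
greater/lesser trochanter bumps) embedded in a soft-tissue ellipse, with
a smoothly varying bone areal density.  Detector counts follow the
two-material Beer-Lambert law at each energy,

    LEi = LE0 * exp(-mu_bone_le * sigma_b - mu_soft_le * sigma_s)

(HE analogous), with optional Poisson or additive Gaussian count noise.
Every phantom carries its ground truth: the 3-class label map
(0 = air, 1 = soft tissue, 2 = bone), the areal-density maps, named ROIs
(femoral neck, Ward's area, greater trochanter) and the true mean BMD of
bone pixels inside each ROI.

Default physical constants are invented but realistic for a ~40/~70 keV
energy pair: bone mass attenuation 0.65/0.25 cm^2/g (LE/HE), soft tissue
0.27/0.20 cm^2/g, bone areal density 0.4-1.4 g/cm^2, soft-tissue areal
density ~2 g/cm^2 (uniform within one scan), incident counts of a few
times 1e4 per pixel.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np
from scipy import ndimage, stats

from .errors import GeometryError, InvalidMetaError
from .io import DualEnergyScan
from .roi import Rect, centered_rect

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_femur_labels",
    "make_density_maps",
    "make_phantom",
    "simulate_scan",
    "make_dataset",
    "default_quality_rois",
    "AIR",
    "SOFT",
    "BONE",
]

AIR, SOFT, BONE = 0, 1, 2


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, materials and acquisition settings of one phantom.

    Geometry is in pixels, referenced to a 128 x 128 image; use
    :meth:`default` to obtain a spec scaled to another shape.
    """

    shape: Tuple[int, int] = (128, 128)
    head_center: Tuple[float, float] = (32.0, 40.0)
    head_radius: float = 14.0
    neck_width: float = 14.0
    shaft_top: float = 60.0
    shaft_length: float = 52.0
    shaft_center_col: float = 78.0
    shaft_width: float = 16.0
    gt_radius: float = 9.0
    lt_radius: float = 5.0
    body_center: Tuple[float, float] = (64.0, 64.0)
    body_axes: Tuple[float, float] = (60.0, 56.0)
    bone_density_range: Tuple[float, float] = (0.4, 1.4)  # g/cm^2
    soft_density_range: Tuple[float, float] = (2.0, 2.0)  # g/cm^2
    mu_bone_le: float = 0.65  # cm^2/g
    mu_bone_he: float = 0.25
    mu_soft_le: float = 0.27
    mu_soft_he: float = 0.20
    he0: float = 50000.0
    le0: float = 40000.0
    pixel_size: float = 0.5  # mm
    noise: str = "poisson"  # "poisson" | "gaussian" | "none"
    gaussian_sigma: float = 50.0  # count units, for noise="gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            self.head_radius, self.neck_width, self.shaft_length,
            self.shaft_width, self.mu_bone_le, self.mu_bone_he,
            self.mu_soft_le, self.mu_soft_he, self.he0, self.le0,
            self.pixel_size,
        ]
        if any(not v > 0 for v in positive):
            raise InvalidMetaError("all physical parameters must be positive")
        if self.gt_radius < 0 or self.lt_radius < 0:
            raise InvalidMetaError("trochanter radii must be >= 0")
        if not (self.mu_bone_le > self.mu_bone_he and self.mu_soft_le > self.mu_soft_he):
            raise InvalidMetaError("attenuation must decrease with energy")
        if not (self.mu_bone_le / self.mu_bone_he > self.mu_soft_le / self.mu_soft_he):
            raise InvalidMetaError(
                "bone LE/HE attenuation ratio must exceed soft tissue's "
                "(dual-energy separability)"
            )
        if self.noise not in ("poisson", "gaussian", "none"):
            raise InvalidMetaError(f"unknown noise model {self.noise!r}")

    @classmethod
    def default(cls, shape: Tuple[int, int] = (128, 128), **overrides) -> "PhantomSpec":
        """Reference spec scaled isotropically to ``shape``."""
        s = min(shape) / 128.0
        geo = dict(
            shape=tuple(shape),
            head_center=(32.0 * s, 40.0 * s),
            head_radius=14.0 * s,
            neck_width=14.0 * s,
            shaft_top=60.0 * s,
            shaft_length=52.0 * s,
            shaft_center_col=78.0 * s,
            shaft_width=16.0 * s,
            gt_radius=9.0 * s,
            lt_radius=5.0 * s,
            body_center=(64.0 * s, 64.0 * s),
            body_axes=(60.0 * s, 56.0 * s),
        )
        geo.update(overrides)
        return cls(**geo)


@dataclass
class PhantomTruth:
    """Ground truth of one phantom."""

    labels: np.ndarray  # int8, {0,1,2}
    bone_density: np.ndarray  # g/cm^2, 0 off bone
    soft_density: np.ndarray  # g/cm^2, 0 on air
    rois: Dict[str, Rect] = field(default_factory=dict)
    true_bmd: Dict[str, float] = field(default_factory=dict)


def _disk(rr, cc, center, radius):
    if radius <= 0:
        return np.zeros(rr.shape, dtype=bool)
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _band(rr, cc, p0, p1, half_width):
    """Pixels within half_width of the segment p0-p1."""
    d = np.array(p1, float) - np.array(p0, float)
    L2 = d @ d
    t = ((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / L2
    t = np.clip(t, 0.0, 1.0)
    pr = p0[0] + t * d[0]
    pc = p0[1] + t * d[1]
    return (rr - pr) ** 2 + (cc - pc) ** 2 <= half_width**2


def _neck_anchor(spec: PhantomSpec) -> tuple[float, float]:
    return (spec.shaft_top + 3.0, spec.shaft_center_col)


def _gt_center(spec: PhantomSpec) -> tuple[float, float]:
    return (
        spec.shaft_top - 4.0 * min(spec.shape) / 128.0,
        spec.shaft_center_col + spec.shaft_width / 2 + spec.gt_radius / 2,
    )


def _lt_center(spec: PhantomSpec) -> tuple[float, float]:
    return (
        spec.shaft_top + 15.0 * min(spec.shape) / 128.0,
        spec.shaft_center_col + spec.shaft_width / 2 + spec.lt_radius / 2,
    )


def make_femur_labels(spec: PhantomSpec) -> np.ndarray:
    """Render the 3-class label map from the parametric femur geometry."""
    h, w = spec.shape
    rr, cc = np.indices((h, w), dtype=float)

    bone = _disk(rr, cc, spec.head_center, spec.head_radius)
    bone |= _band(rr, cc, spec.head_center, _neck_anchor(spec), spec.neck_width / 2)
    r0, r1 = spec.shaft_top, spec.shaft_top + spec.shaft_length
    c0 = spec.shaft_center_col - spec.shaft_width / 2
    c1 = spec.shaft_center_col + spec.shaft_width / 2
    bone |= (rr >= r0) & (rr < r1) & (cc >= c0) & (cc < c1)
    bone |= _disk(rr, cc, _gt_center(spec), spec.gt_radius)
    bone |= _disk(rr, cc, _lt_center(spec), spec.lt_radius)

    (br, bc) = spec.body_center
    (ar, ac) = spec.body_axes
    body_val = ((rr - br) / ar) ** 2 + ((cc - bc) / ac) ** 2
    body = body_val <= 1.0

    if bone.any():
        rows, cols = np.nonzero(bone)
        if rows.min() < 1 or cols.min() < 1 or rows.max() >= h - 1 or cols.max() >= w - 1:
            raise GeometryError("bone geometry touches the image border")
        if (body_val[bone] >= 0.995).any():
            raise GeometryError("bone is not strictly inside the soft-tissue body")
    if not body.any():
        raise GeometryError("soft-tissue body outside the image")

    labels = np.zeros((h, w), dtype=np.int8)
    labels[body] = SOFT
    labels[bone] = BONE
    return labels


def make_density_maps(
    labels: np.ndarray, spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Areal-density maps consistent with a label map.

    Bone density is a smooth low-frequency random field, rank-mapped to a
    uniform distribution over ``spec.bone_density_range`` on bone pixels
    and exactly 0 elsewhere.  The rank map gives every phantom the same
    bone-density histogram (a controlled-population design, as in
    calibrated step phantoms) while the spatial pattern still varies, so
    regional mean densities differ between phantoms and ROIs.

    Soft-tissue density is uniform over the body (a constant drawn from
    ``spec.soft_density_range``; the default range is degenerate at
    2.0 g/cm^2, the uniform-phantom convention) and 0 on air.  It also
    covers bone pixels, since the beam there traverses overlying soft
    tissue as well.
    """
    labels = np.asarray(labels)
    h, w = labels.shape
    bone = labels == BONE
    body = labels >= SOFT

    bone_density = np.zeros((h, w), dtype=float)
    if bone.any():
        lo, hi = spec.bone_density_range
        coarse = rng.standard_normal((9, 9))
        fld = ndimage.zoom(coarse, (h / 9, w / 9), order=3)[:h, :w]
        vals = fld[bone]
        if hi == lo or np.unique(vals).size == 1:
            bone_density[bone] = lo
        else:
            ranks = stats.rankdata(vals, method="average") - 1.0
            bone_density[bone] = lo + (hi - lo) * ranks / ranks.max()

    soft_density = np.zeros((h, w), dtype=float)
    if body.any():
        lo, hi = spec.soft_density_range
        soft_density[body] = rng.uniform(lo, hi)

    return bone_density, soft_density


def _default_rois(spec: PhantomSpec) -> Dict[str, Rect]:
    s = min(spec.shape) / 128.0
    anchor = _neck_anchor(spec)
    neck_mid = (
        (spec.head_center[0] + anchor[0]) / 2,
        (spec.head_center[1] + anchor[1]) / 2,
    )
    gt = _gt_center(spec)
    ward = (
        (spec.head_center[0] + anchor[0] + gt[0]) / 3,
        (spec.head_center[1] + anchor[1] + gt[1]) / 3,
    )
    rois = {
        "neck": centered_rect(*neck_mid, max(int(round(spec.neck_width + 2 * s)), 4)),
        "ward": centered_rect(*ward, max(int(round(10 * s)), 4)),
        "gt": centered_rect(*gt, max(int(round(2 * spec.gt_radius - 2 * s)), 4)),
    }
    for name, r in rois.items():
        if not r.inside(spec.shape):
            raise GeometryError(f"ROI {name} = {r} outside image {spec.shape}")
    return rois


def make_phantom(spec: PhantomSpec, rng: np.random.Generator) -> PhantomTruth:
    """Labels, density maps, ROIs and true per-ROI BMD for one phantom."""
    labels = make_femur_labels(spec)
    bone_density, soft_density = make_density_maps(labels, spec, rng)
    rois = _default_rois(spec)
    true_bmd = {}
    bone = labels == BONE
    for name, r in rois.items():
        sel = r.extract(bone)
        if sel.any():
            true_bmd[name] = float(r.extract(bone_density)[sel].mean())
    return PhantomTruth(labels, bone_density, soft_density, rois, true_bmd)


def simulate_scan(
    truth: PhantomTruth, spec: PhantomSpec, rng: np.random.Generator | None = None
) -> DualEnergyScan:
    """Beer-Lambert expected counts plus the configured count noise.

    Counts are clamped to >= 1 after noise so downstream logarithms stay
    finite.
    """
    if truth.labels.shape != tuple(spec.shape):
        raise InvalidMetaError("truth shape inconsistent with spec shape")
    sb, ss = truth.bone_density, truth.soft_density
    le = spec.le0 * np.exp(-spec.mu_bone_le * sb - spec.mu_soft_le * ss)
    he = spec.he0 * np.exp(-spec.mu_bone_he * sb - spec.mu_soft_he * ss)
    if spec.noise != "none":
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        if spec.noise == "poisson":
            le = rng.poisson(le).astype(float)
            he = rng.poisson(he).astype(float)
        elif spec.noise == "gaussian":
            le = le + rng.normal(0.0, spec.gaussian_sigma, le.shape)
            he = he + rng.normal(0.0, spec.gaussian_sigma, he.shape)
        else:  # pragma: no cover - spec validation already rejects this
            raise InvalidMetaError(f"unknown noise model {spec.noise!r}")
    le = np.maximum(le, 1.0)
    he = np.maximum(he, 1.0)
    return DualEnergyScan(
        he=he, le=le, he0=spec.he0, le0=spec.le0,
        u_l=spec.mu_bone_le, u_h=spec.mu_bone_he, pixel_size=spec.pixel_size,
    )


def _jitter_spec(spec: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Per-item geometry jitter emulating patient-to-patient variation."""
    s = min(spec.shape) / 128.0
    u = lambda a: float(rng.uniform(-a, a)) * s
    return replace(
        spec,
        head_center=(spec.head_center[0] + u(2.0), spec.head_center[1] + u(2.0)),
        head_radius=spec.head_radius + u(1.5),
        neck_width=spec.neck_width + u(1.5),
        shaft_length=spec.shaft_length + u(3.0),
        shaft_width=spec.shaft_width + u(1.5),
        shaft_center_col=spec.shaft_center_col + u(1.5),
        gt_radius=max(spec.gt_radius + u(1.0), 0.0),
        lt_radius=max(spec.lt_radius + u(1.0), 0.0),
    )


def make_dataset(
    n: int, spec: PhantomSpec | None = None, seed: int = 0
) -> list[tuple[DualEnergyScan, PhantomTruth]]:
    """n phantoms with jittered geometry and fresh density fields/noise."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    spec = spec or PhantomSpec.default()
    root = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        item_spec = _jitter_spec(spec, rng)
        truth = make_phantom(item_spec, rng)
        scan = simulate_scan(truth, item_spec, rng)
        out.append((scan, truth))
    return out


def default_quality_rois(spec: PhantomSpec | None = None) -> tuple[Rect, Rect]:
    """(object ROI, background ROI) for quality metrics.

    Object = 10x10 square inscribed in the shaft bone; background = air
    patch of the same size at the image corner, so the two ROIs have the
    equal areas SNR/CNR require.  Both shrink proportionally for smaller
    phantoms.
    """
    spec = spec or PhantomSpec.default()
    side = max(int(round(10 * min(spec.shape) / 128.0)), 4)
    side = min(side, int(spec.shaft_width) - 2)
    r0 = int(round(spec.shaft_top + spec.shaft_length / 2 - side / 2))
    c0 = int(round(spec.shaft_center_col - side / 2))
    obj = Rect(r0, r0 + side, c0, c0 + side)
    bg = Rect(2, 2 + side, 2, 2 + side)
    if not (obj.inside(spec.shape) and bg.inside(spec.shape)):
        raise GeometryError("default quality ROIs fall outside the image")
    return obj, bg
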