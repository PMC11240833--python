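"""Pixel-wise 3-class segmentation of display images.

Two segmenters are provided:

* :func:`baseline_segment` — deterministic two-threshold classification
  by 3-class between-class variance maximization (multi-Otsu) on the
  image histogram, assuming intensity ordering air < soft tissue < bone
  (true of the bone-density and collage display images);
* :func:`train_segmenter` — a small trainable encoder-decoder (NumPy,
  see :mod:`dxafemur._nn`) optimized with Adadelta under the weighted
  cross-entropy loss

      H = -(1/n_pix) * sum_pix sum_c w_c * y_c * ln(max(ŷ_c, 1e-7)),

  with per-class weights defaulting to inverse class frequency (unit
  weights recover the plain cross-entropy).

Plus dataset augmentation (translation / flips / scaling, the identical
geometric transform applied to image and mask) and morphological
binary smoothing of predicted masks.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu
from skimage.morphology import closing, disk, opening

from ._nn import Adadelta, TinyEncoderDecoder
from .contrast import DisplayImage
from .errors import ShapeMismatchError

__all__ = [
    "AugmentConfig",
    "TrainConfig",
    "augment_dataset",
    "hflip",
    "vflip",
    "weighted_cross_entropy",
    "baseline_segment",
    "train_segmenter",
    "predict_mask",
    "smooth_mask",
    "SegmenterModel",
]

N_CLASSES = 3


# --------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------
@dataclass(frozen=True)
class AugmentConfig:
    """Geometric augmentation settings.

    ``multiplier`` is the dataset expansion factor; when ``target_count``
    is set, the expanded list is truncated to exactly that many pairs
    (e.g. 350 inputs x 6 -> truncated to 1800).
    """

    max_translation: int = 10
    hflip: bool = True
    vflip: bool = True
    scale_range: Tuple[float, float] = (0.9, 1.1)
    multiplier: int = 1
    target_count: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")
        if not (0 < self.scale_range[0] <= self.scale_range[1]):
            raise ValueError("scale range must be a positive interval")
        if self.max_translation < 0:
            raise ValueError("max_translation must be >= 0")


def hflip(arr: np.ndarray) -> np.ndarray:
    """Horizontal (left-right) reflection; an involution."""
    return arr[:, ::-1].copy()


def vflip(arr: np.ndarray) -> np.ndarray:
    """Vertical (up-down) reflection; an involution."""
    return arr[::-1, :].copy()


def _scale_about_center(arr: np.ndarray, factor: float, order: int) -> np.ndarray:
    """Zoom by ``factor`` and crop/pad back to the original shape."""
    h, w = arr.shape
    zoomed = ndimage.zoom(arr, factor, order=order, mode="constant", cval=0)
    zh, zw = zoomed.shape
    out = np.zeros_like(arr)
    if zh >= h:
        r0, c0 = (zh - h) // 2, (zw - w) // 2
        out[:, :] = zoomed[r0 : r0 + h, c0 : c0 + w]
    else:
        r0, c0 = (h - zh) // 2, (w - zw) // 2
        out[r0 : r0 + zh, c0 : c0 + zw] = zoomed
    return out


def _random_transform(
    img: np.ndarray, mask: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """One random geometric transform applied identically to both arrays.

    Masks use nearest-neighbor resampling (order 0) so labels stay in
    {0,1,2}; vacated border pixels become air (0)."""
    out_i, out_m = img.astype(float), mask.copy()
    if cfg.hflip and rng.random() < 0.5:
        out_i, out_m = hflip(out_i), hflip(out_m)
    if cfg.vflip and rng.random() < 0.5:
        out_i, out_m = vflip(out_i), vflip(out_m)
    lo, hi = cfg.scale_range
    if hi > lo or lo != 1.0:
        factor = float(rng.uniform(lo, hi))
        if factor != 1.0:
            out_i = _scale_about_center(out_i, factor, order=1)
            out_m = _scale_about_center(out_m, factor, order=0)
    if cfg.max_translation > 0:
        dr = int(rng.integers(-cfg.max_translation, cfg.max_translation + 1))
        dc = int(rng.integers(-cfg.max_translation, cfg.max_translation + 1))
        out_i = ndimage.shift(out_i, (dr, dc), order=1, mode="constant", cval=0)
        out_m = ndimage.shift(out_m, (dr, dc), order=0, mode="constant", cval=0)
    return out_i, out_m.astype(mask.dtype)


def augment_dataset(
    pairs: Sequence[Tuple[np.ndarray, np.ndarray]], cfg: AugmentConfig
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Expand (image, mask) pairs by ``cfg.multiplier``.

    Each input contributes itself plus multiplier-1 randomly transformed
    copies; the result is reproducible from ``cfg.seed`` and truncated to
    ``cfg.target_count`` when set.
    """
    if len(pairs) == 0:
        raise ValueError("empty input dataset")
    rng = np.random.default_rng(cfg.seed)
    out: List[Tuple[np.ndarray, np.ndarray]] = []
    for img, mask in pairs:
        img = np.asarray(img)
        mask = np.asarray(mask)
        if img.shape != mask.shape:
            raise ShapeMismatchError(f"image {img.shape} vs mask {mask.shape}")
        out.append((img, mask))
        for _ in range(cfg.multiplier - 1):
            out.append(_random_transform(img, mask, cfg, rng))
    if cfg.target_count is not None:
        out = out[: cfg.target_count]
    return out


# --------------------------------------------------------------------
# loss
# --------------------------------------------------------------------
def _onehot(mask: np.ndarray) -> np.ndarray:
    return (np.arange(N_CLASSES)[:, None, None] == mask[None, :, :]).astype(float)


def weighted_cross_entropy(
    pred: np.ndarray, truth: np.ndarray, weights: Sequence[float] | None = None
) -> float:
    """Weighted cross-entropy H between score maps and a label mask.

    ``pred`` is (3, H, W); scores are clipped to [1e-7, 1] before the
    log.  Unit weights (the default) give the plain multiclass
    cross-entropy averaged over pixels.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth)
    if pred.shape != (N_CLASSES,) + truth.shape:
        raise ShapeMismatchError(
            f"pred {pred.shape} incompatible with truth {truth.shape}"
        )
    w = np.ones(N_CLASSES) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (N_CLASSES,) or (w <= 0).any():
        raise ValueError("weights must be 3 positive reals")
    y = _onehot(truth)
    logp = np.log(np.clip(pred, 1e-7, 1.0))
    return float(-np.einsum("chw,c,chw->", y, w, logp) / truth.size)


# --------------------------------------------------------------------
# baseline segmenter
# --------------------------------------------------------------------
def baseline_segment(img: DisplayImage | np.ndarray) -> np.ndarray:
    """Two-threshold 3-class segmentation by histogram variance analysis.

    Deterministic multi-Otsu thresholding with classes ordered by
    intensity (air darkest, bone brightest).  A constant image carries
    no contrast and maps to all-air.
    """
    pix = img.pixels if isinstance(img, DisplayImage) else np.asarray(img, dtype=float)
    if pix.max() == pix.min():
        return np.zeros(pix.shape, dtype=np.int8)
    thresholds = threshold_multiotsu(pix, classes=3)
    return np.digitize(pix, bins=thresholds).astype(np.int8)


# --------------------------------------------------------------------
# trainable encoder-decoder
# --------------------------------------------------------------------
@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adadelta"
    batch_size: int = 25
    initial_lr: float = 0.2
    epochs: int = 200
    lr_factor: float = 0.5
    lr_patience: int = 10
    class_weights: object = "inverse-frequency"  # or a 3-sequence of reals
    channels: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.optimizer != "adadelta":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if not isinstance(self.class_weights, str):
            w = np.asarray(self.class_weights, dtype=float)
            if w.shape != (N_CLASSES,) or (w <= 0).any():
                raise ValueError("class_weights must be 3 positive reals")


class SegmenterModel:
    """Handle around a trained :class:`TinyEncoderDecoder`.

    Exposes the per-epoch training curve and the input normalization
    used during training.
    """

    def __init__(self, net: TinyEncoderDecoder, class_weights: np.ndarray):
        self.net = net
        self.class_weights = class_weights
        self.history: List[float] = []
        self.lr_trace: List[float] = []

    def predict_proba(self, img: np.ndarray) -> np.ndarray:
        x = (np.asarray(img, dtype=float) - self.net.in_shift) / self.net.in_scale
        return self.net.predict_proba(x)


def _inverse_frequency_weights(masks: Sequence[np.ndarray]) -> np.ndarray:
    counts = np.zeros(N_CLASSES)
    for m in masks:
        counts += np.bincount(np.asarray(m).ravel(), minlength=N_CLASSES)[:N_CLASSES]
    present = counts > 0
    w = np.ones(N_CLASSES)
    w[present] = counts[present].sum() / (present.sum() * counts[present])
    # absent classes never contribute to the loss; keep a finite weight
    w[~present] = 1.0
    return w


def train_segmenter(
    train_pairs: Sequence[Tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig | None = None,
) -> SegmenterModel:
    """Train the small encoder-decoder on (display image, mask) pairs.

    Images must share one even-sided shape.  Inputs are affinely mapped
    to [0, 1] using the training set's range; the mapping is stored on
    the model.  The learning rate is halved when the epoch loss has not
    improved for ``lr_patience`` epochs (reduce-on-plateau).
    """
    cfg = cfg or TrainConfig()
    if len(train_pairs) == 0:
        raise ValueError("empty training set")
    shapes = {np.asarray(img).shape for img, _ in train_pairs}
    if len(shapes) != 1:
        raise ShapeMismatchError(f"inconsistent training shapes: {shapes}")
    (h, w) = shapes.pop()
    if h % 2 or w % 2:
        raise ValueError("image sides must be even (one 2x pooling stage)")
    imgs = np.stack([np.asarray(i, dtype=float) for i, _ in train_pairs])
    masks = np.stack([np.asarray(m) for _, m in train_pairs])
    if masks.min() < 0 or masks.max() >= N_CLASSES:
        raise ValueError("mask labels must be in {0,1,2}")

    if isinstance(cfg.class_weights, str):
        if cfg.class_weights != "inverse-frequency":
            raise ValueError(f"unknown class_weights {cfg.class_weights!r}")
        class_w = _inverse_frequency_weights(masks)
    else:
        class_w = np.asarray(cfg.class_weights, dtype=float)

    net = TinyEncoderDecoder(channels=cfg.channels, seed=cfg.seed)
    net.in_shift = float(imgs.min())
    net.in_scale = float(imgs.max() - imgs.min()) or 1.0
    x_all = (imgs - net.in_shift) / net.in_scale
    y_all = np.stack([_onehot(m) for m in masks])

    model = SegmenterModel(net, class_w)
    opt = Adadelta(net.params, lr=cfg.initial_lr)
    rng = np.random.default_rng(cfg.seed)
    best = np.inf
    stale = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(len(train_pairs))
        total = 0.0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads = net.loss_and_grads(
                x_all[idx][:, None, :, :], y_all[idx], class_w
            )
            opt.step(net.params, grads)
            total += loss * len(idx)
        epoch_loss = total / len(order)
        model.history.append(epoch_loss)
        model.lr_trace.append(opt.lr)
        if epoch_loss < best - 1e-12:
            best = epoch_loss
            stale = 0
        else:
            stale += 1
            if stale >= cfg.lr_patience:
                opt.lr *= cfg.lr_factor
                stale = 0
    return model


def predict_mask(model: SegmenterModel, img: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """(probability maps, label mask); ties resolve bone > soft > air."""
    probs = model.predict_proba(np.asarray(img, dtype=float))
    mask = _argmax_bone_first(probs)
    return probs, mask


def _argmax_bone_first(scores: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over (3,H,W) scores, ties going to the higher
    class (bone > soft tissue > air)."""
    rev = scores[::-1]  # bone, soft, air
    return (N_CLASSES - 1 - rev.argmax(axis=0)).astype(np.int8)


# --------------------------------------------------------------------
# post-processing
# --------------------------------------------------------------------
def smooth_mask(mask: np.ndarray, radius: int = 2) -> np.ndarray:
    """Morphological binary smoothing of a 3-class mask.

    Each class indicator is opened then closed with a disk structuring
    element; the smoothed indicators are recombined by per-pixel argmax
    with ties between claiming classes resolved bone > soft tissue > air.
    A pixel claimed by no smoothed indicator keeps its input label, so
    the output is always a valid partition.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    mask = np.asarray(mask)
    se = disk(radius)
    smoothed = np.stack(
        [
            closing(opening(mask == c, se), se)
            for c in range(N_CLASSES)
        ]
    ).astype(np.int8)
    out = _argmax_bone_first(smoothed)
    unclaimed = smoothed.sum(axis=0) == 0
    out[unclaimed] = mask[unclaimed]
    return out
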