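"""Segmentation scoring, threshold-gated dataset accuracy, cross-validation
folds, BMD extraction per ROI, and R² agreement between measurement sets.

Per class c (one-vs-rest over the pixel grid):

    JI    = |A ∩ B| / |A ∪ B|          (Jaccard index / IoU)
    Dice  = 2|A ∩ B| / (|A| + |B|)     (DISC)
    ε     = 100 · TP / (TP + FN)       (sensitivity, %)
    ϑ     = 100 · TN / (TN + FP)       (specificity, %)

An image "passes" when the bone-class scores clear all three gates
(JI ≥ 0.92, ε ≥ 95, ϑ ≥ 93); dataset accuracy is 100 × the pass
fraction.  A ``ji_variant="printed"`` option evaluates the literal
|A∩B|/(|A|+|B|) form (which is bounded by 0.5 and cannot clear a 0.92
gate) for study purposes; the default is the standard Jaccard index.

Empty-class conventions: a class absent from both masks scores
JI = Dice = 1; absent from exactly one, 0.  Sensitivity/specificity with
an empty denominator default to 100 (nothing to miss / nothing to
falsely include); FPR/FNR default to 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .contrast import make_ibd
from .errors import ShapeMismatchError
from .io import DualEnergyScan
from .phantom import BONE, PhantomTruth
from .roi import Rect

__all__ = [
    "class_confusion",
    "overlap_scores",
    "mean_dice",
    "image_pass",
    "dataset_accuracy",
    "kfold_split",
    "bmd_map",
    "roi_bmd",
    "r_squared",
    "score_masks",
    "evaluate_dataset",
    "ScoreCard",
    "EvalSummary",
    "BMDResult",
    "DEFAULT_THRESHOLDS",
]

CLASSES = (0, 1, 2)
DEFAULT_THRESHOLDS = (0.92, 95.0, 93.0)


def _check_masks(pred: np.ndarray, truth: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ShapeMismatchError(f"pred {pred.shape} vs truth {truth.shape}")
    return pred, truth


def class_confusion(pred: np.ndarray, truth: np.ndarray, c: int) -> Tuple[int, int, int, int]:
    """One-vs-rest pixel counts (TP, TN, FP, FN) for class ``c``."""
    pred, truth = _check_masks(pred, truth)
    a = pred == c
    b = truth == c
    tp = int(np.count_nonzero(a & b))
    fp = int(np.count_nonzero(a & ~b))
    fn = int(np.count_nonzero(~a & b))
    tn = a.size - tp - fp - fn
    return tp, tn, fp, fn


def overlap_scores(
    pred: np.ndarray, truth: np.ndarray, c: int, ji_variant: str = "standard"
) -> Tuple[float, float, float, float, float, float]:
    """(JI, Dice, sensitivity %, specificity %, FPR, FNR) for class ``c``."""
    tp, tn, fp, fn = class_confusion(pred, truth, c)
    union = tp + fp + fn
    size_sum = 2 * tp + fp + fn  # |A| + |B|
    if union == 0:  # class absent from both masks
        ji = dice = 1.0
    else:
        if ji_variant == "printed":
            ji = tp / size_sum
        elif ji_variant == "standard":
            ji = tp / union
        else:
            raise ValueError(f"unknown ji_variant {ji_variant!r}")
        dice = 2 * tp / size_sum
    eps = 100.0 * tp / (tp + fn) if tp + fn else 100.0
    theta = 100.0 * tn / (tn + fp) if tn + fp else 100.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    fnr = fn / (fn + tp) if fn + tp else 0.0
    return ji, dice, eps, theta, fpr, fnr


def mean_dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Arithmetic mean of the per-class Dice scores over the 3 classes."""
    return float(
        np.mean([overlap_scores(pred, truth, c)[1] for c in CLASSES])
    )


def image_pass(
    ji: float,
    eps: float,
    theta: float,
    thresholds: Tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> int:
    """1 iff all three gates are met (conjunctive, boundary inclusive)."""
    if not 0.0 <= ji <= 1.0:
        raise ValueError(f"JI must be in [0,1], got {ji}")
    if not (0.0 <= eps <= 100.0 and 0.0 <= theta <= 100.0):
        raise ValueError("sensitivity/specificity must be in [0,100]")
    tj, te, tt = thresholds
    return int(ji >= tj and eps >= te and theta >= tt)


def dataset_accuracy(
    scores: Sequence[Tuple[float, float, float]],
    thresholds: Tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> float:
    """100 x fraction of images whose (JI, ε, ϑ) clear all gates."""
    if len(scores) == 0:
        raise ValueError("empty score list")
    return 100.0 * float(
        np.mean([image_pass(*s, thresholds=thresholds) for s in scores])
    )


def kfold_split(n: int, k: int = 5, seed: int = 0) -> List[Tuple[np.ndarray, np.ndarray]]:
    """k shuffled folds of range(n): list of (train_idx, test_idx).

    Test sets are disjoint, cover all indices, and have sizes
    ceil(n/k) or floor(n/k).
    """
    if n < k:
        raise ValueError(f"need n >= k, got n={n}, k={k}")
    perm = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(perm, k)
    out = []
    for i, test in enumerate(folds):
        train = np.concatenate([folds[j] for j in range(k) if j != i])
        out.append((np.sort(train), np.sort(test)))
    return out


def bmd_map(scan: DualEnergyScan) -> np.ndarray:
    """Per-pixel BMD: exactly the bone-density display image's pixels."""
    return make_ibd(scan).pixels


@dataclass
class BMDResult:
    """Mean BMD over bone-labeled pixels inside each named ROI."""

    values: Dict[str, float] = field(default_factory=dict)  # present ROIs only
    counts: Dict[str, int] = field(default_factory=dict)  # all ROIs


def roi_bmd(bmd: np.ndarray, mask: np.ndarray, rois: Dict[str, Rect]) -> BMDResult:
    """Mean of ``bmd`` over bone pixels inside each ROI.

    ROIs without any bone pixel are reported absent (count 0, no value).
    """
    bmd, mask = _check_masks(np.asarray(bmd, dtype=float), mask)
    res = BMDResult()
    for name, rect in rois.items():
        sel = rect.extract(mask) == BONE
        n = int(np.count_nonzero(sel))
        res.counts[name] = n
        if n:
            res.values[name] = float(rect.extract(bmd)[sel].mean())
    return res


def r_squared(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation between two equal-length sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    if x.size < 2:
        raise ValueError("need at least two points")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance in x or y")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class ScoreCard:
    """Per-class confusion counts and overlap/rate metrics for one image."""

    confusion: Dict[int, Tuple[int, int, int, int]] = field(default_factory=dict)
    ji: Dict[int, float] = field(default_factory=dict)
    dice: Dict[int, float] = field(default_factory=dict)
    sensitivity: Dict[int, float] = field(default_factory=dict)
    specificity: Dict[int, float] = field(default_factory=dict)
    fpr: Dict[int, float] = field(default_factory=dict)
    fnr: Dict[int, float] = field(default_factory=dict)
    mean_dice: float = 0.0


def score_masks(pred: np.ndarray, truth: np.ndarray) -> ScoreCard:
    """Full per-class scoring of one predicted mask against ground truth."""
    card = ScoreCard()
    for c in CLASSES:
        card.confusion[c] = class_confusion(pred, truth, c)
        ji, dice, eps, theta, fpr, fnr = overlap_scores(pred, truth, c)
        card.ji[c] = ji
        card.dice[c] = dice
        card.sensitivity[c] = eps
        card.specificity[c] = theta
        card.fpr[c] = fpr
        card.fnr[c] = fnr
    card.mean_dice = float(np.mean([card.dice[c] for c in CLASSES]))
    return card


@dataclass
class EvalSummary:
    """Dataset-level segmentation summary.

    ``accuracy_pct`` is the threshold-gated statistic on the bone class;
    ``pixel_accuracy_pct`` (plain fraction of correctly labeled pixels)
    is reported alongside since published summary tables do not say which
    of the two they print.
    """

    cards: List[ScoreCard] = field(default_factory=list)
    accuracy_pct: float = 0.0
    mean_disc_pct: float = 0.0
    pixel_accuracy_pct: float = 0.0
    thresholds: Tuple[float, float, float] = DEFAULT_THRESHOLDS


def evaluate_dataset(
    preds: Sequence[np.ndarray],
    truths: Sequence[np.ndarray],
    thresholds: Tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> EvalSummary:
    """Score every (pred, truth) pair and pool the dataset statistics."""
    if len(preds) != len(truths) or len(preds) == 0:
        raise ValueError("preds and truths must be equal-length and nonempty")
    summary = EvalSummary(thresholds=thresholds)
    gate_scores = []
    correct = total = 0
    for pred, truth in zip(preds, truths):
        card = score_masks(pred, truth)
        summary.cards.append(card)
        gate_scores.append(
            (card.ji[BONE], card.sensitivity[BONE], card.specificity[BONE])
        )
        pred, truth = _check_masks(pred, truth)
        correct += int(np.count_nonzero(pred == truth))
        total += pred.size
    summary.accuracy_pct = dataset_accuracy(gate_scores, thresholds)
    summary.mean_disc_pct = 100.0 * float(np.mean([c.mean_dice for c in summary.cards]))
    summary.pixel_accuracy_pct = 100.0 * correct / total
    return summary
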