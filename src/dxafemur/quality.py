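"""Image-quality metrics (MSR, SNR, CNR) and before/after reporting.

Conventions: MSR divides the mean of the *entire* image by the standard
deviation inside a background ROI (default 10x10); SNR and CNR are
amplitude ratios in decibels, 20*log10(.); all standard deviations are
population (ddof = 0) so oracle hand computations are exact.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateRoiError, ShapeMismatchError
from .roi import Rect

__all__ = ["msr", "snr_db", "cnr_db", "quality_report", "QualityReport"]


def msr(img: np.ndarray, bg_roi: Rect) -> float:
    """Mean of the whole image over the std within the background ROI."""
    img = np.asarray(img, dtype=float)
    sigma = bg_roi.extract(img).std()
    if sigma == 0.0:
        raise DegenerateRoiError(f"zero std in background ROI {bg_roi}")
    return float(img.mean() / sigma)


def snr_db(img: np.ndarray, object_roi: Rect, bg_roi: Rect) -> float:
    """20*log10(mean object intensity / background std), in dB."""
    img = np.asarray(img, dtype=float)
    if object_roi.area != bg_roi.area:
        raise DegenerateRoiError(
            f"object ROI area {object_roi.area} != background ROI area {bg_roi.area}"
        )
    mu_obj = object_roi.extract(img).mean()
    sigma = bg_roi.extract(img).std()
    if sigma == 0.0:
        raise DegenerateRoiError(f"zero std in background ROI {bg_roi}")
    if mu_obj <= 0.0:
        raise DegenerateRoiError(f"non-positive object mean {mu_obj}")
    return float(20.0 * np.log10(mu_obj / sigma))


def cnr_db(img: np.ndarray, object_roi: Rect, bg_roi: Rect) -> float:
    """20*log10(|mean object - mean background| / background std), in dB."""
    img = np.asarray(img, dtype=float)
    if object_roi.area != bg_roi.area:
        raise DegenerateRoiError(
            f"object ROI area {object_roi.area} != background ROI area {bg_roi.area}"
        )
    mu_obj = object_roi.extract(img).mean()
    bg = bg_roi.extract(img)
    mu_bg, sigma = bg.mean(), bg.std()
    if sigma == 0.0:
        raise DegenerateRoiError(f"zero std in background ROI {bg_roi}")
    if mu_obj == mu_bg:
        raise DegenerateRoiError("object and background means are equal")
    return float(20.0 * np.log10(abs(mu_obj - mu_bg) / sigma))


@dataclass
class QualityReport:
    """MSR/SNR/CNR of an original and a denoised image on shared ROIs."""

    technique: str
    metrics: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    object_roi: Rect | None = None
    bg_roi: Rect | None = None

    @property
    def ratios(self) -> Dict[str, float]:
        """Improvement ratio denoised/original per metric."""
        return {k: v[1] / v[0] for k, v in self.metrics.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"Technique": self.technique, "Index": name,
             "Original": orig, "Denoised": den}
            for name, (orig, den) in self.metrics.items()
        ]
        return pd.DataFrame(rows, columns=["Technique", "Index", "Original", "Denoised"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "QualityReport":
        df = pd.read_csv(path)
        rep = cls(technique=str(df["Technique"].iloc[0]))
        for _, row in df.iterrows():
            rep.metrics[str(row["Index"])] = (float(row["Original"]), float(row["Denoised"]))
        return rep


def quality_report(
    original: np.ndarray,
    denoised: np.ndarray,
    object_roi: Rect,
    bg_roi: Rect,
    technique: str = "",
) -> QualityReport:
    """All three metrics on both images, computed on identical ROIs."""
    original = np.asarray(original, dtype=float)
    denoised = np.asarray(denoised, dtype=float)
    if original.shape != denoised.shape:
        raise ShapeMismatchError(
            f"original {original.shape} vs denoised {denoised.shape}"
        )
    rep = QualityReport(technique=technique, object_roi=object_roi, bg_roi=bg_roi)
    rep.metrics["MSR"] = (msr(original, bg_roi), msr(denoised, bg_roi))
    rep.metrics["SNR"] = (
        snr_db(original, object_roi, bg_roi),
        snr_db(denoised, object_roi, bg_roi),
    )
    rep.metrics["CNR"] = (
        cnr_db(original, object_roi, bg_roi),
        cnr_db(denoised, object_roi, bg_roi),
    )
    return rep
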