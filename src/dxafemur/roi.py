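"""Rectangular regions of interest.

Convention used everywhere in the toolkit: row-major, 0-based, half-open
rectangles ``[r0, r1) x [c0, c1)``.
"""
from __future__ import annotations

from typing import NamedTuple

import numpy as np


class Rect(NamedTuple):
    """Half-open axis-aligned rectangle [r0, r1) x [c0, c1)."""

    r0: int
    r1: int
    c0: int
    c1: int

    @property
    def shape(self) -> tuple[int, int]:
        return (self.r1 - self.r0, self.c1 - self.c0)

    @property
    def area(self) -> int:
        return max(self.r1 - self.r0, 0) * max(self.c1 - self.c0, 0)

    def inside(self, shape: tuple[int, int]) -> bool:
        return (
            0 <= self.r0 < self.r1 <= shape[0]
            and 0 <= self.c0 < self.c1 <= shape[1]
        )

    def extract(self, img: np.ndarray) -> np.ndarray:
        """Slice of ``img`` covered by this rectangle (a view)."""
        if not self.inside(img.shape[:2]):
            raise ValueError(f"ROI {self} outside image of shape {img.shape}")
        return img[self.r0 : self.r1, self.c0 : self.c1]


def centered_rect(center_r: float, center_c: float, side: int) -> Rect:
    """Square Rect of given side centered (to pixel precision) at a point."""
    r0 = int(round(center_r - side / 2))
    c0 = int(round(center_c - side / 2))
    return Rect(r0, r0 + side, c0, c0 + side)
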