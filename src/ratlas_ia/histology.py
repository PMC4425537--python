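"""Optical-density quantification of immunostained sections.

Staining density is measured as the number of pixels above a threshold of
twice the background intensity inside a standardized ROI box, and compared
between the concussed (ipsilateral) and control (contralateral) hemispheres
with two-tailed paired t-tests (animal as the experimental unit; slices are
averaged per animal first).

If the stain is darker than background (true optical density), invert the
image before measurement (``invert_image``); polarity is a configuration
choice, not hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ROIBox",
    "ODMeasurement",
    "estimate_background",
    "measure_od",
    "paired_od_test",
    "invert_image",
]

DEFAULT_THRESHOLD_FACTOR = 2.0


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned pixel box: origin (x, y) plus width and height."""

    x: int
    y: int
    width: int
    height: int

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y, self.y + self.height), slice(self.x, self.x + self.width)

    @property
    def area(self) -> int:
        return self.width * self.height

    def validate(self, image: np.ndarray) -> None:
        h, w = image.shape[:2]
        if self.width <= 0 or self.height <= 0:
            raise ValueError("empty ROI")
        if self.x < 0 or self.y < 0 or self.x + self.width > w or self.y + self.height > h:
            raise ValueError(f"ROI {self} outside {w}x{h} image")

    def to_dict(self) -> dict:
        return {"x": self.x, "y": self.y, "width": self.width, "height": self.height}

    @classmethod
    def from_dict(cls, d: dict) -> "ROIBox":
        return cls(int(d["x"]), int(d["y"]), int(d["width"]), int(d["height"]))


@dataclass
class ODMeasurement:
    roi: ROIBox
    background: float
    threshold: float
    count: int
    area: int

    def __post_init__(self) -> None:
        if self.count > self.area:
            raise ValueError("above-threshold count exceeds ROI area")


def invert_image(image: np.ndarray) -> np.ndarray:
    """Flip intensity polarity (dark stain -> bright stain)."""
    image = np.asarray(image, dtype=float)
    return image.max() - image


def estimate_background(image: np.ndarray, background_roi: ROIBox) -> float:
    """Median intensity of the designated background ROI (robust to speckle)."""
    image = np.asarray(image)
    background_roi.validate(image)
    return float(np.median(image[background_roi.slices()]))


def measure_od(
    image: np.ndarray,
    roi: ROIBox,
    threshold: float,
    background: float | None = None,
) -> ODMeasurement:
    """Count pixels strictly above ``threshold`` inside ``roi``."""
    image = np.asarray(image)
    roi.validate(image)
    patch = image[roi.slices()]
    count = int((patch > threshold).sum())
    return ODMeasurement(
        roi=roi,
        background=float("nan") if background is None else float(background),
        threshold=float(threshold),
        count=count,
        area=roi.area,
    )


def check_standardized(rois: list[ROIBox]) -> None:
    """All ROIs entering one paired comparison must share dimensions."""
    dims = {(r.width, r.height) for r in rois}
    if len(dims) > 1:
        raise ValueError(f"ROIs are not of standardized size: {sorted(dims)}")


def paired_od_test(
    ipsi_counts: np.ndarray, contra_counts: np.ndarray
) -> dict[str, float]:
    """Two-tailed paired t-test on per-animal above-threshold counts.

    Returns t, two-tailed p, and the fold-change mean(ipsi)/mean(contra)
    (NaN-flagged when the contralateral mean is zero).
    """
    ipsi = np.asarray(ipsi_counts, dtype=float)
    contra = np.asarray(contra_counts, dtype=float)
    if ipsi.shape != contra.shape:
        raise ValueError("paired lists must have equal length")
    if ipsi.size < 2:
        raise ValueError("need at least 2 animals for a paired test")
    diff = ipsi - contra
    if np.allclose(diff.std(ddof=1), 0.0):
        t, p = (0.0, 1.0) if np.allclose(diff.mean(), 0.0) else (np.inf * np.sign(diff.mean()), 0.0)
    else:
        t, p = sps.ttest_rel(ipsi, contra)
    fold = float(ipsi.mean() / contra.mean()) if contra.mean() != 0 else float("nan")
    return {"t": float(t), "p": float(p), "fold_change": fold, "n": int(ipsi.size)}
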