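"""Cell detection in the transmitted-light channel.

A deterministic classical chain (Gaussian smoothing, gradient magnitude,
Otsu threshold on the gradient, morphological closing, hole filling)
stands in for a trained pixel classifier; objects are then classified by
size into singlet / clump / debris and filtered by a membership
probability and a border test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology
from skimage.measure import label, regionprops

__all__ = [
    "SegmentationConfig",
    "CellObject",
    "pixel_classify",
    "classify_objects",
    "filter_singlets",
]


@dataclass(frozen=True)
class SegmentationConfig:
    gradient_smooth_sigma: float = 1.5
    area_min_singlet: int = 300
    area_max_singlet: int = 3000
    prob_threshold: float = 0.5
    border_margin: int = 0
    # compensates the outward dilation of the gradient-band mask so object
    # areas track the true footprint
    post_erosion_radius: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.area_min_singlet < self.area_max_singlet:
            raise ValueError("require 0 < area_min_singlet < area_max_singlet")
        if not 0 <= self.prob_threshold < 1:
            raise ValueError("require 0 <= prob_threshold < 1")


@dataclass
class CellObject:
    """A segmented 8-connected component."""

    label: int
    coords: np.ndarray  # (n, 2) array of (row, col) pixel coordinates
    area: int
    centroid: tuple[float, float]  # (x, y) = (col, row), 0-based
    cls: str  # singlet | clump | debris
    class_prob: float
    touches_border: bool


def pixel_classify(trans: np.ndarray,
                   config: SegmentationConfig = SegmentationConfig()) -> np.ndarray:
    """Binary foreground mask from edge detection on the transmitted channel."""
    img = np.asarray(trans, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=bool)
    # reflect-pad so border-truncated objects keep touching the edge after
    # the morphological steps (the erosion must not detach them)
    pad = 16
    padded = np.pad(img, pad, mode="reflect")
    smoothed = filters.gaussian(padded, sigma=config.gradient_smooth_sigma,
                                preserve_range=True)
    grad = filters.sobel(smoothed)
    if np.ptp(grad) == 0:
        return np.zeros(img.shape, dtype=bool)
    thr = filters.threshold_otsu(grad)
    mask = grad > thr
    mask = morphology.closing(mask, morphology.disk(2))
    mask = ndi.binary_fill_holes(mask)
    if config.post_erosion_radius > 0:
        mask = morphology.erosion(
            mask, morphology.disk(config.post_erosion_radius))
    return mask[pad:-pad, pad:-pad]


def _singlet_prob(area: float, config: SegmentationConfig) -> float:
    """Triangular membership: 1.0 at the window midpoint, 0.5 at its edges."""
    lo, hi = config.area_min_singlet, config.area_max_singlet
    mid = (lo + hi) / 2.0
    if area <= mid:
        p = 0.5 + 0.5 * (area - lo) / (mid - lo)
    else:
        p = 0.5 + 0.5 * (hi - area) / (hi - mid)
    return float(min(max(p, 1e-6), 1.0))


def classify_objects(mask: np.ndarray,
                     config: SegmentationConfig = SegmentationConfig()) -> list[CellObject]:
    """Label 8-connected components and classify them by area."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    lab = label(mask, connectivity=2)
    out: list[CellObject] = []
    for rp in regionprops(lab):
        area = int(rp.area)
        if area < config.area_min_singlet:
            cls, prob = "debris", 1.0
        elif area > config.area_max_singlet:
            cls, prob = "clump", 1.0
        else:
            cls, prob = "singlet", _singlet_prob(area, config)
        rmin, cmin, rmax, cmax = rp.bbox
        m = config.border_margin
        touches = (rmin <= m or cmin <= m
                   or rmax >= h - m or cmax >= w - m)
        cy, cx = rp.centroid
        out.append(CellObject(
            label=int(rp.label), coords=rp.coords.copy(), area=area,
            centroid=(float(cx), float(cy)), cls=cls, class_prob=prob,
            touches_border=bool(touches)))
    return out


def filter_singlets(objects: list[CellObject],
                    config: SegmentationConfig = SegmentationConfig()) -> list[CellObject]:
    """Retain singlets with class_prob strictly above threshold, off-border."""
    return [o for o in objects
            if o.cls == "singlet"
            and o.class_prob > config.prob_threshold
            and not o.touches_border]
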