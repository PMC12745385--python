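"""ROI localization and slice standardization.

The spinal canal is localized without any learned model: the left-right
intensity balance of whole columns identifies the midline, the slice is
split into four quadrants at (height/2, midline), the quadrant with the
brightest midline-proximal band is kept, and that region is recursively
bisected perpendicular to its longer side, always keeping the half with the
higher midline-band mean.  The final region is expanded symmetrically to a
minimum side length.  All coordinates are 0-based, half-open [start, stop),
with the row index increasing downward.

Contrast is then standardized by classical global histogram equalization
inside the ROI, and the crop is resized to 224 x 224 in [0, 1] for the
feature extractors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

__all__ = [
    "RoiConfig",
    "ROIBox",
    "find_midline",
    "quadrant_roi",
    "equalize_hist",
    "standardize_slice",
    "STANDARD_SIZE",
]

STANDARD_SIZE = 224


@dataclass(frozen=True)
class RoiConfig:
    midline_search_band: float = 0.5   # fraction of width searched, centered
    band_width_frac: float = 0.2       # midline-proximal band width / width
    recursion_depth: int = 2
    min_roi_side: int = 64

    def __post_init__(self) -> None:
        for f in (self.midline_search_band, self.band_width_frac):
            if not 0 < f <= 1:
                raise ValueError("fractions must be in (0, 1]")
        if self.recursion_depth < 0:
            raise ValueError("recursion_depth must be >= 0")
        if self.min_roi_side < 1:
            raise ValueError("min_roi_side must be >= 1")


@dataclass(frozen=True)
class ROIBox:
    """Half-open rectangle [row_start, row_stop) x [col_start, col_stop)."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int
    score: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_stop):
            raise ValueError("need 0 <= row_start < row_stop")
        if not (0 <= self.col_start < self.col_stop):
            raise ValueError("need 0 <= col_start < col_stop")

    @property
    def height(self) -> int:
        return self.row_stop - self.row_start

    @property
    def width(self) -> int:
        return self.col_stop - self.col_start

    @property
    def area(self) -> int:
        return self.height * self.width

    def contains(self, row: float, col: float) -> bool:
        return (self.row_start <= row < self.row_stop
                and self.col_start <= col < self.col_stop)

    def crop(self, img: np.ndarray) -> np.ndarray:
        return np.asarray(img)[self.row_start:self.row_stop,
                               self.col_start:self.col_stop]


def _as_image(img) -> np.ndarray:
    a = np.asarray(img, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite values")
    return a


def midline_candidates(width: int, search_band: float) -> np.ndarray:
    """Candidate split columns: both sides nonempty, within the centered
    search band."""
    half = search_band * width / 2.0
    lo = max(1, int(np.ceil(width / 2.0 - half)))
    hi = min(width - 1, int(np.floor(width / 2.0 + half)))
    return np.arange(lo, hi + 1)


def find_midline(img, cfg: RoiConfig = RoiConfig()) -> int:
    """Split column minimizing |mean(left columns) - mean(right columns)|.

    Ties are broken toward the column nearest width/2, then the smaller
    index.  Invariant to adding a constant to the image.
    """
    a = _as_image(img)
    h, w = a.shape
    if w < 8:
        raise ValueError("image must be at least 8 columns wide")

    col_sums = a.sum(axis=0)
    csum = np.concatenate([[0.0], np.cumsum(col_sums)])
    total = csum[-1]
    cand = midline_candidates(w, cfg.midline_search_band)
    left_mean = csum[cand] / (cand * h)
    right_mean = (total - csum[cand]) / ((w - cand) * h)
    obj = np.abs(left_mean - right_mean)

    best = obj.min()
    tied = cand[np.isclose(obj, best, rtol=0.0, atol=1e-12)]
    center_dist = np.abs(tied - w / 2.0)
    tied = tied[center_dist == center_dist.min()]
    return int(tied.min())


def _band_mean(a: np.ndarray, region: tuple, band: tuple) -> float:
    """Mean intensity of a region restricted to the midline column band;
    falls back to the whole region when it misses the band."""
    r0, r1, c0, c1 = region
    b0, b1 = max(c0, band[0]), min(c1, band[1])
    if b0 >= b1:
        return float(a[r0:r1, c0:c1].mean())
    return float(a[r0:r1, b0:b1].mean())


def quadrant_roi(img, cfg: RoiConfig = RoiConfig()) -> ROIBox:
    """Quadrant-based ROI: keep the quadrant (then recursively the half)
    with the highest mean intensity in the vertical band around the
    midline, then expand to at least ``min_roi_side`` per side."""
    a = _as_image(img)
    h, w = a.shape
    if h < cfg.min_roi_side or w < cfg.min_roi_side:
        raise ValueError(
            f"image {a.shape} smaller than min_roi_side={cfg.min_roi_side}")

    m = find_midline(a, cfg)
    half_band = max(1, int(round(cfg.band_width_frac * w / 2.0)))
    band = (max(0, m - half_band), min(w, m + half_band))

    rm, cm = h // 2, m
    quadrants = [(0, rm, 0, cm), (0, rm, cm, w), (rm, h, 0, cm), (rm, h, cm, w)]
    quadrants = [q for q in quadrants if q[1] > q[0] and q[3] > q[2]]
    region = max(quadrants, key=lambda q: _band_mean(a, q, band))

    for _ in range(cfg.recursion_depth):
        r0, r1, c0, c1 = region
        if r1 - r0 <= 2 and c1 - c0 <= 2:
            break
        if (r1 - r0) >= (c1 - c0):       # bisect the longer side
            mid = (r0 + r1) // 2
            halves = [(r0, mid, c0, c1), (mid, r1, c0, c1)]
        else:
            mid = (c0 + c1) // 2
            halves = [(r0, r1, c0, mid), (r0, r1, mid, c1)]
        halves = [q for q in halves if q[1] > q[0] and q[3] > q[2]]
        region = max(halves, key=lambda q: _band_mean(a, q, band))

    r0, r1, c0, c1 = region
    r0, r1 = _expand(r0, r1, cfg.min_roi_side, h)
    c0, c1 = _expand(c0, c1, cfg.min_roi_side, w)
    return ROIBox(r0, r1, c0, c1, score=_band_mean(a, (r0, r1, c0, c1), band))


def _expand(start: int, stop: int, min_side: int, extent: int) -> tuple:
    """Symmetrically grow [start, stop) to at least min_side within
    [0, extent)."""
    side = stop - start
    if side >= min_side:
        return start, stop
    grow = min(min_side, extent) - side
    start = start - grow // 2
    stop = stop + (grow - grow // 2)
    if start < 0:
        stop -= start
        start = 0
    if stop > extent:
        start -= stop - extent
        stop = extent
    return max(0, start), stop


def equalize_hist(img, n_bins: int = 256) -> np.ndarray:
    """Classical global histogram equalization.

    Pixels are quantized to ``n_bins`` levels over the image's own range and
    mapped through the normalized empirical CDF, a monotone non-decreasing
    gray-level mapping with output in [0, 1].  Constant images map to a
    constant.
    """
    a = _as_image(img)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.full_like(a, a.flat[0] if 0 <= a.flat[0] <= 1 else 1.0)
    q = np.minimum((n_bins * (a - lo) / (hi - lo)).astype(int), n_bins - 1)
    counts = np.bincount(q.ravel(), minlength=n_bins)
    cdf = np.cumsum(counts) / q.size
    return cdf[q]


def standardize_slice(img, roi: ROIBox | None = None,
                      out_size: int = STANDARD_SIZE) -> np.ndarray:
    """Crop to the ROI, equalize, bilinearly resize to ``out_size`` square
    and min-max rescale to [0, 1] (a constant crop maps to all zeros)."""
    a = _as_image(img)
    if roi is not None:
        h, w = a.shape
        if roi.row_stop > h or roi.col_stop > w:
            raise ValueError(f"roi {roi} exceeds image shape {a.shape}")
        a = roi.crop(a)
    if a.size == 0:
        raise ValueError("degenerate roi: empty crop")
    a = equalize_hist(a)
    a = resize(a, (out_size, out_size), order=1, mode="edge",
               anti_aliasing=False, preserve_range=True)
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.zeros((out_size, out_size))
    return (a - lo) / (hi - lo)
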