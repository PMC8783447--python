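"""Per-section thresholding and circular Hough transform (CHT) detection.

GUV cross-sections appear as bright circular contours in each z-section.
Segmentation proceeds in two steps: a binary mask built from a triangle-
method histogram threshold (which makes detection robust at low
signal-to-noise ratio), then a CHT over a configured radius range that
scores the likelihood of a circle of radius r at every pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

#: Radius bounds (px) that cover typical GUV sizes at the default calibration.
DEFAULT_RADIUS_RANGE_PX = (20, 120)

#: Duplicate suppression: two detections closer than this in center AND radius
#: are considered one circle; the higher-scoring one is kept.
_DEDUP_CENTER_PX = 2.0
_DEDUP_RADIUS_PX = 2.0
#: Concentric suppression: a candidate whose center falls within this fraction
#: of a kept circle's radius is the same object seen at another radius.
_NMS_OVERLAP_FRAC = 0.75


@dataclass
class CircleDetection:
    """One circle found in one z-section: the segmentation atom."""

    z_index: int
    cx: float
    cy: float
    r: float
    score: float = 0.0

    def bbox_inside(self, shape: tuple[int, int]) -> bool:
        h, w = shape
        return (
            self.cx - self.r >= 0
            and self.cy - self.r >= 0
            and self.cx + self.r <= w - 1
            and self.cy + self.r <= h - 1
        )


def triangular_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Triangle-method threshold on a histogram of the observed range.

    Builds an ``nbins`` equal-width histogram, draws the line from the peak
    bin to the farthest non-empty tail bin, and returns the intensity (bin
    center) maximizing the perpendicular distance from the histogram curve
    to that line.

    Raises
    ------
    ValueError
        If the image is constant (no threshold definable).
    """
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if lo == hi:
        raise ValueError("constant image: no threshold definable")
    # integer-valued data (e.g. 16-bit camera counts): keep bin width >= 1,
    # otherwise empty comb bins between discrete levels distort the geometry
    if np.all(image == np.rint(image)):
        nbins = min(nbins, int(hi - lo) + 1)
    counts, edges = np.histogram(image, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])

    peak = int(np.argmax(counts))
    nonzero = np.flatnonzero(counts)
    # farthest non-empty bin from the peak, on either side
    tail = nonzero[np.argmax(np.abs(nonzero - peak))]
    if tail == peak:
        raise ValueError("degenerate histogram: all mass in one bin")

    lo_i, hi_i = (peak, tail) if peak < tail else (tail, peak)
    idx = np.arange(lo_i, hi_i + 1)
    # perpendicular point-to-line distance in (bin index, count) space
    x1, y1 = float(peak), float(counts[peak])
    x2, y2 = float(tail), float(counts[tail])
    num = np.abs((y2 - y1) * idx - (x2 - x1) * counts[idx] + x2 * y1 - y2 * x1)
    best = idx[int(np.argmax(num))]
    return float(centers[best])


def make_binary_mask(image: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask: pixel true iff its intensity exceeds the threshold."""
    return np.asarray(image) > threshold


def _edge_map(image: np.ndarray, use_mask: bool) -> np.ndarray:
    """Edge pixels feeding the Hough accumulator.

    Default path masks the image first (triangle threshold) and takes the
    gradient magnitude of the binary mask; the raw-image path runs Canny on
    the normalized intensities.
    """
    image = np.asarray(image, dtype=float)
    if use_mask:
        try:
            thr = triangular_threshold(image)
        except ValueError:
            return np.zeros(image.shape, dtype=bool)
        mask = make_binary_mask(image, thr).astype(float)
        gy = ndimage.sobel(mask, axis=0)
        gx = ndimage.sobel(mask, axis=1)
        return np.hypot(gx, gy) > 0
    rng = image.max() - image.min()
    if rng == 0:
        return np.zeros(image.shape, dtype=bool)
    return canny((image - image.min()) / rng, sigma=1.5)


def _refine_radius(
    image: np.ndarray, cx: float, cy: float, r: float, window: float = 6.0
) -> float:
    """Snap a coarse radius onto the intensity crest of the ring.

    Mask-based Hough votes sit on the mask boundary, which lies a few px
    outside the blurred ring's crest; the crest itself is the argmax of the
    circularly averaged radial intensity profile, refined to sub-pixel by a
    parabolic fit around the peak bin.
    """
    h, w = image.shape
    lo = max(r - window, 1.0)
    hi = r + window
    yy, xx = np.mgrid[0:h, 0:w]
    d = np.hypot(xx - cx, yy - cy)
    sel = (d >= lo - 0.5) & (d <= hi + 0.5)
    if not sel.any():
        return r
    bins = np.round(d[sel]).astype(int)
    vals = np.asarray(image, dtype=float)[sel]
    lo_i, hi_i = int(bins.min()), int(bins.max())
    sums = np.bincount(bins - lo_i, weights=vals, minlength=hi_i - lo_i + 1)
    counts = np.bincount(bins - lo_i, minlength=hi_i - lo_i + 1)
    profile = sums / np.maximum(counts, 1)
    k = int(np.argmax(profile))
    refined = float(lo_i + k)
    if 0 < k < len(profile) - 1:
        a, b, c = profile[k - 1], profile[k], profile[k + 1]
        denom = a - 2 * b + c
        if denom < 0:
            refined += 0.5 * (a - c) / denom
    return refined


def detect_circles(
    image: np.ndarray,
    radius_range: tuple[int, int] = DEFAULT_RADIUS_RANGE_PX,
    sensitivity: float = 0.5,
    z_index: int = 0,
    use_mask: bool = True,
    radius_step: int = 1,
    max_circles: int = 200,
) -> list[CircleDetection]:
    """Detect candidate circles in one section with a two-stage CHT.

    Edge pixels vote for centers at each candidate radius; accumulator peaks
    above a sensitivity-scaled fraction of the theoretical maximum become
    detections.  ``sensitivity`` is a 0-1 knob: a peak is accepted when its
    normalized accumulator value is at least ``1 - sensitivity``, so higher
    sensitivity admits lower-score (more tentative) circles.

    Returns circles sorted by descending score, with near-duplicates
    (center distance < 2 px and radius difference < 2 px) suppressed.
    """
    r_min, r_max = radius_range
    if r_min < 1 or r_min > r_max:
        raise ValueError(f"invalid radius range {radius_range}")
    if not 0.0 <= sensitivity <= 1.0:
        raise ValueError("sensitivity must lie in [0, 1]")

    edges = _edge_map(image, use_mask)
    if not edges.any():
        return []
    radii = np.arange(r_min, r_max + 1, radius_step)
    accum = hough_circle(edges, radii, normalize=True, full_output=False)
    threshold = max(1.0 - sensitivity, 1e-6)
    scores, cxs, cys, rs = hough_circle_peaks(
        accum,
        radii,
        min_xdistance=1,
        min_ydistance=1,
        threshold=threshold,
        total_num_peaks=max(2000, max_circles),
        normalize=False,
    )
    order = np.argsort(-np.asarray(scores), kind="stable")
    kept: list[CircleDetection] = []
    for i in order:
        cand = CircleDetection(
            z_index=z_index,
            cx=float(cxs[i]),
            cy=float(cys[i]),
            r=float(rs[i]),
            score=float(scores[i]),
        )
        dup = False
        for k in kept:
            center_d = np.hypot(cand.cx - k.cx, cand.cy - k.cy)
            if center_d < _DEDUP_CENTER_PX and abs(cand.r - k.r) < _DEDUP_RADIUS_PX:
                dup = True
                break
            # same object re-detected at a nearby radius: candidate center
            # sits deep inside an already-kept (higher-scoring) circle
            if center_d < _NMS_OVERLAP_FRAC * min(cand.r, k.r):
                dup = True
                break
        if not dup:
            kept.append(cand)
        if len(kept) >= max_circles:
            break
    image_f = np.asarray(image, dtype=float)
    for det in kept:
        det.r = float(
            np.clip(_refine_radius(image_f, det.cx, det.cy, det.r), r_min, r_max)
        )
    return kept
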