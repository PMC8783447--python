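"""Pixel-membership primitives shared by the measurement modules.

Conventions (fixed package-wide): 0-based pixel indices, pixel centers at
integer coordinates, ``x`` = column, ``y`` = row, ``z`` = page index.
Angles are measured in degrees from the +x axis, increasing with
``atan2(y - cy, x - cx)``.
"""

from __future__ import annotations

import numpy as np


def distance_grid(shape: tuple[int, int], cx: float, cy: float) -> np.ndarray:
    """Euclidean distance of every pixel center from (cx, cy), in px."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(xx - cx, yy - cy)


def angle_grid(shape: tuple[int, int], cx: float, cy: float) -> np.ndarray:
    """Angle of every pixel center around (cx, cy), degrees in [0, 360)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0


def disc_mask(shape: tuple[int, int], cx: float, cy: float, r: float) -> np.ndarray:
    """Pixels with center distance d <= r."""
    return distance_grid(shape, cx, cy) <= r


def annulus_mask(
    shape: tuple[int, int], cx: float, cy: float, r: float, band_px: float
) -> np.ndarray:
    """Pixels with r - band_px < d <= r (the membrane band, inward)."""
    d = distance_grid(shape, cx, cy)
    return (d > r - band_px) & (d <= r)


def wedge_mask(
    shape: tuple[int, int],
    cx: float,
    cy: float,
    r: float,
    delta_r: float,
    theta_lo: float,
    theta_hi: float,
) -> np.ndarray:
    """Annular wedge: r - delta_r < d <= r and theta in [theta_lo, theta_hi).

    Angles in degrees; the wedge wraps correctly across 360.
    """
    d = distance_grid(shape, cx, cy)
    ang = angle_grid(shape, cx, cy)
    radial = (d > r - delta_r) & (d <= r)
    lo = theta_lo % 360.0
    hi = theta_hi % 360.0
    if lo < hi:
        angular = (ang >= lo) & (ang < hi)
    else:  # wraps through 0
        angular = (ang >= lo) | (ang < hi)
    return radial & angular


def circle_inside_image(
    cx: float, cy: float, r: float, shape: tuple[int, int]
) -> bool:
    """True iff the circle's bounding square lies fully inside the image."""
    h, w = shape
    return (cx - r >= 0) and (cy - r >= 0) and (cx + r <= w - 1) and (cy + r <= h - 1)
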