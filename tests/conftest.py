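"""Shared fixtures: tiny synthetic images built independently of the package.

The ring/disc painters here are deliberately separate from the simulator so
that segmentation and intensity tests check the package against independent
constructions.
"""

from __future__ import annotations

import numpy as np
import pytest


def paint_ring(
    shape: tuple[int, int],
    cx: float,
    cy: float,
    r: float,
    level: float = 1000.0,
    background: float = 0.0,
    width: float = 1.0,
) -> np.ndarray:
    """Ring of the given width painted by per-pixel distance, no blur."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.hypot(xx - cx, yy - cy)
    img = np.full(shape, background, dtype=float)
    img[np.abs(d - r) <= width / 2.0] = level
    return img


def paint_disc(
    shape: tuple[int, int],
    cx: float,
    cy: float,
    r: float,
    level: float = 500.0,
    background: float = 0.0,
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, background, dtype=float)
    img[np.hypot(xx - cx, yy - cy) <= r] = level
    return img


def paint_half_ring(
    shape: tuple[int, int],
    cx: float,
    cy: float,
    r: float,
    right_level: float,
    left_level: float,
    width: float = 3.0,
) -> np.ndarray:
    """Ring whose right half (|angle| < 90 deg) and left half differ."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.hypot(xx - cx, yy - cy)
    on_ring = np.abs(d - r) <= width / 2.0
    img = np.zeros(shape, dtype=float)
    img[on_ring & (xx >= cx)] = right_level
    img[on_ring & (xx < cx)] = left_level
    return img


@pytest.fixture
def rng():
    return np.random.default_rng(42)
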