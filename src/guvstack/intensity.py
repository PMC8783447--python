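"""Membrane-bound and droplet fluorescence quantification.

Geometry (center, radius) comes from the detection channel A; intensities
are measured in the analysis channel B.  Every raw sum is corrected for the
camera/solution background with the net-intensity rule

    I_net = I_raw - I_background

where the background is a per-pixel level estimated from the dark part of
each section image (mean of the pixels at or below the triangle threshold).
Negative nets are reported as-is, which keeps condition means unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import annulus_mask, disc_mask
from .segment import CircleDetection, triangular_threshold

DEFAULT_INWARD_PX = 3


@dataclass
class BindingResult:
    """Per-vesicle membrane-binding intensities (channel B)."""

    vesicle_id: int
    per_section: list[tuple[float, float, int]] = field(default_factory=list)
    #: pixel-count-weighted mean of the per-section per-px nets

    @property
    def vesicle_mean_per_px(self) -> float:
        totals = sum(t for t, _, _ in self.per_section)
        n = sum(n for _, _, n in self.per_section)
        return totals / n


@dataclass
class DropletResult:
    """Per-droplet interior intensities."""

    droplet_id: int
    per_section: list[tuple[float, int]] = field(default_factory=list)

    @property
    def droplet_mean_per_px(self) -> float:
        total = sum(m * n for m, n in self.per_section)
        n = sum(n for _, n in self.per_section)
        return total / n


def estimate_background(image: np.ndarray) -> float:
    """Per-pixel background: mean of pixels at or below the triangle threshold.

    A constant image is its own background.
    """
    image = np.asarray(image, dtype=float)
    try:
        thr = triangular_threshold(image)
    except ValueError:
        return float(image.flat[0])
    dark = image[image <= thr]
    return float(dark.mean())


def net_intensity(raw: float, background_per_px: float, n_px: int) -> float:
    """Background-corrected total: raw - background_per_px * n_px."""
    if n_px < 1:
        raise ValueError("n_px must be >= 1")
    return raw - background_per_px * n_px


def membrane_intensity(
    image: np.ndarray,
    circle: CircleDetection,
    inward_px: int = DEFAULT_INWARD_PX,
    background_per_px: float = 0.0,
) -> tuple[float, float, int]:
    """Net channel-B intensity over the membrane band of one circle.

    The band is the set of pixels whose center distance d from (cx, cy)
    satisfies r - inward_px < d <= r.  Returns
    ``(total_net, per_px_net, pixel_count)``.
    """
    if inward_px < 1:
        raise ValueError("inward_px must be >= 1")
    if not circle.bbox_inside(image.shape):
        raise ValueError("circle extends outside the image")
    band = annulus_mask(image.shape, circle.cx, circle.cy, circle.r, inward_px)
    n = int(band.sum())
    if n == 0:
        raise ValueError("no pixels in the membrane band")
    raw = float(np.asarray(image, dtype=float)[band].sum())
    total_net = net_intensity(raw, background_per_px, n)
    return total_net, total_net / n, n


def droplet_interior_intensity(
    image: np.ndarray,
    circle: CircleDetection,
    background_per_px: float = 0.0,
) -> tuple[float, int]:
    """Net mean per px over the whole disc d <= r (droplet interior).

    Protein droplets hold their cargo throughout the volume, so the entire
    area inside the circle is measured rather than just the periphery.
    """
    if not circle.bbox_inside(image.shape):
        raise ValueError("circle extends outside the image")
    disc = disc_mask(image.shape, circle.cx, circle.cy, circle.r)
    n = int(disc.sum())
    mean_raw = float(np.asarray(image, dtype=float)[disc].mean())
    return mean_raw - background_per_px, n


def measure_entity_binding(
    channel_b: np.ndarray | list[np.ndarray],
    entity,
    inward_px: int = DEFAULT_INWARD_PX,
    backgrounds: list[float] | None = None,
) -> BindingResult:
    """Measure every section of a grouped entity in channel B.

    ``channel_b`` is indexable by z; ``backgrounds`` gives the per-section
    background level (estimated per section image when omitted).
    """
    result = BindingResult(vesicle_id=entity.vesicle_id)
    for circ in entity.sections:
        img = channel_b[circ.z_index]
        bg = (
            backgrounds[circ.z_index]
            if backgrounds is not None
            else estimate_background(img)
        )
        total, per_px, n = membrane_intensity(img, circ, inward_px, bg)
        result.per_section.append((total, per_px, n))
    return result


def condition_summary(stack_means: list[float]) -> tuple[float, float]:
    """Condition mean and between-stack standard deviation.

    Each element of ``stack_means`` is one image stack's mean (e.g. the mean
    of its vesicles' per-px nets).  The SD uses the n-1 denominator; with a
    single stack it is undefined and reported as NaN.
    """
    if len(stack_means) < 1:
        raise ValueError("need at least one stack")
    mean = float(np.mean(stack_means))
    sd = float(np.std(stack_means, ddof=1)) if len(stack_means) > 1 else float("nan")
    return mean, sd
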