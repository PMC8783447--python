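"""Phase-separation state determination from contour intensity profiles.

A lipid reporter partitions unevenly between coexisting membrane domains,
so a phase-separated vesicle shows two intensity levels along its membrane
contour while a homogeneous one is uniform.  The perimeter of each detected
circle is divided into N angular segments; the per-segment net mean
intensities form a :class:`ContourProfile`.  Domain "high" and "low" levels
are read off at a percentile rank of the sorted segment means, and a
hysteresis traversal counts directional swings spanning the full +/-p% band
around the mid-intensity — each swing is one domain boundary.  A section is
"separated" when it has at least two such discontinuities (a closed contour
crossing into a domain must cross back out), and a vesicle is "separated"
when at least a set fraction (default 40%) of its sections are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import angle_grid, distance_grid
from .segment import CircleDetection

DEFAULT_N_SEGMENTS = 36
DEFAULT_DELTA_R_PX = 3
DEFAULT_PERCENTILE = 20.0
DEFAULT_P_PERCENT = 20.0
DEFAULT_DECISION_FRACTION = 0.40

UNIFORM = "uniform"
SEPARATED = "separated"


@dataclass
class ContourProfile:
    """Ordered per-angular-segment net mean intensities around one circle."""

    segment_means: np.ndarray
    delta_r: float = DEFAULT_DELTA_R_PX
    theta0: float = 0.0

    def __post_init__(self) -> None:
        self.segment_means = np.asarray(self.segment_means, dtype=float)

    @property
    def n_segments(self) -> int:
        return len(self.segment_means)


@dataclass
class PhaseDecision:
    """Per-vesicle phase-state decision with its per-section evidence."""

    vesicle_id: int
    per_section_state: list[str]
    fraction_separated: float
    vesicle_state: str
    per_section_levels: list[tuple[float, float, float]] = field(default_factory=list)


def contour_profile(
    image: np.ndarray,
    circle: CircleDetection,
    n_segments: int = DEFAULT_N_SEGMENTS,
    delta_r: float = DEFAULT_DELTA_R_PX,
    background_per_px: float = 0.0,
    theta0: float = 0.0,
) -> ContourProfile:
    """Mean net intensity per angular segment of the membrane annulus.

    Segment k collects pixels with center distance in (r - delta_r, r] and
    angle in [theta0 + k*360/N, theta0 + (k+1)*360/N), angles measured from
    the +x axis in the direction of increasing ``atan2(y - cy, x - cx)``.

    Raises
    ------
    ValueError
        If any segment holds no pixel (choose smaller N or larger delta_r).
    """
    if n_segments < 8:
        raise ValueError("need at least 8 segments")
    if delta_r < 1:
        raise ValueError("delta_r must be >= 1 px")
    if not circle.bbox_inside(image.shape):
        raise ValueError("circle extends outside the image")
    image = np.asarray(image, dtype=float)
    d = distance_grid(image.shape, circle.cx, circle.cy)
    ang = angle_grid(image.shape, circle.cx, circle.cy)
    radial = (d > circle.r - delta_r) & (d <= circle.r)
    rel = (ang - theta0) % 360.0
    seg_idx = np.floor(rel / (360.0 / n_segments)).astype(int)
    seg_idx = np.clip(seg_idx, 0, n_segments - 1)  # guards rel == 360-eps rounding

    means = np.empty(n_segments)
    for k in range(n_segments):
        sel = radial & (seg_idx == k)
        if not sel.any():
            raise ValueError(
                f"segment {k} is empty; use fewer segments or a larger delta_r"
            )
        means[k] = image[sel].mean() - background_per_px
    return ContourProfile(means, delta_r=delta_r, theta0=theta0)


def domain_levels(
    profile: ContourProfile, percentile: float = DEFAULT_PERCENTILE
) -> tuple[float, float, float]:
    """(high, low, mid) domain intensity levels from the sorted segments.

    Sorting the segment means descending, ``high`` is the value at rank
    ceil(percentile/100 * N) from the top and ``low`` the value at the same
    rank from the bottom; ``mid`` is their midpoint.  The percentile guards
    against single-segment outliers defining a domain level.
    """
    if not 0 < percentile < 50:
        raise ValueError("percentile must lie in (0, 50)")
    means = profile.segment_means
    n = len(means)
    rank = math.ceil(percentile / 100.0 * n)
    desc = np.sort(means)[::-1]
    high = float(desc[rank - 1])
    low = float(desc[n - rank])
    return high, low, (high + low) / 2.0


def detect_discontinuities(
    profile: ContourProfile, mid: float, p: float = DEFAULT_P_PERCENT
) -> int:
    """Count directional intensity swings spanning the +/-p% band around mid.

    Traversal follows increasing theta cyclically with two-state hysteresis:
    the trace is HIGH after last exceeding mid*(1 + p/100) and LOW after
    last dropping below mid*(1 - p/100); each HIGH->LOW or LOW->HIGH
    transition is one discontinuity (a domain boundary).  On a closed
    contour the count is even by construction.  A trace that never leaves
    the dead band has zero discontinuities.
    """
    if p <= 0:
        raise ValueError("p must be positive")
    if mid <= 0:
        raise ValueError("mid-intensity must be positive (no dynamic range)")
    means = profile.segment_means
    hi_thr = mid * (1.0 + p / 100.0)
    lo_thr = mid * (1.0 - p / 100.0)
    labels = np.zeros(len(means), dtype=int)
    labels[means > hi_thr] = 1
    labels[means < lo_thr] = -1
    decided = labels[labels != 0]
    if decided.size < 2:
        return 0
    # transitions around the full cycle of decided states
    return int(np.count_nonzero(decided != np.roll(decided, 1)))


def section_state(
    profile: ContourProfile,
    percentile: float = DEFAULT_PERCENTILE,
    p: float = DEFAULT_P_PERCENT,
) -> str:
    """Classify one section's contour as uniform or separated.

    Separated iff the profile shows at least two discontinuities (a single
    domain on a closed contour produces an entry and an exit crossing).
    A profile with no dynamic range (high == low) is uniform outright.
    """
    high, low, mid = domain_levels(profile, percentile)
    if high == low or mid <= 0:
        return UNIFORM
    return SEPARATED if detect_discontinuities(profile, mid, p) >= 2 else UNIFORM


def vesicle_state(
    states: list[str],
    decision_fraction: float = DEFAULT_DECISION_FRACTION,
    vesicle_id: int = 0,
    levels: list[tuple[float, float, float]] | None = None,
) -> PhaseDecision:
    """Vesicle-level decision from its per-section states.

    The vesicle is phase-separated when at least ``decision_fraction`` of
    its z-sections are (boundary inclusive; the default 0.40 means 2 of 5
    separated sections suffice).
    """
    if not states:
        raise ValueError("need at least one section state")
    frac = sum(s == SEPARATED for s in states) / len(states)
    return PhaseDecision(
        vesicle_id=vesicle_id,
        per_section_state=list(states),
        fraction_separated=frac,
        vesicle_state=SEPARATED if frac >= decision_fraction else UNIFORM,
        per_section_levels=levels or [],
    )
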