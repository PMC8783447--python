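"""Group per-section circles into 3-D vesicle entities and filter them.

A GUV appears as a short run of concentric circles across adjacent
z-sections.  Grouping links circles whose centers agree within a tolerance,
tracking the most recent section's center so that slow drift is tolerated.
Two selection stages then reject ill-formed candidates: a per-circle
edge-contrast filter (removes filled/multilamellar-looking sections) and
per-entity rules (minimum section count, edge-touching exclusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import annulus_mask, disc_mask
from .segment import CircleDetection

DEFAULT_CENTER_TOLERANCE_PX = 10.0
DEFAULT_MIN_SECTIONS = 3
DEFAULT_BAND_PX = 3
DEFAULT_MIN_EDGE_RATIO = 1.5

STATUS_ACCEPTED = "accepted"


@dataclass
class VesicleEntity:
    """A grouped set of circle detections forming one 3-D GUV or droplet."""

    vesicle_id: int
    sections: list[CircleDetection] = field(default_factory=list)
    status: str = STATUS_ACCEPTED
    per_section_metrics: list[dict] = field(default_factory=list)

    @property
    def n_sections(self) -> int:
        return len(self.sections)

    @property
    def accepted(self) -> bool:
        return self.status == STATUS_ACCEPTED

    @property
    def mean_radius(self) -> float:
        return float(np.mean([c.r for c in self.sections]))

    def last_center(self) -> tuple[float, float]:
        return self.sections[-1].cx, self.sections[-1].cy


def edge_contrast_filter(
    image: np.ndarray,
    circle: CircleDetection,
    band_px: float = DEFAULT_BAND_PX,
    min_ratio: float = DEFAULT_MIN_EDGE_RATIO,
) -> tuple[bool, dict]:
    """Pass a circle iff its rim is bright relative to its interior.

    The rim is the annulus (r - band_px, r] of pixel-center distances; the
    interior is the disc of radius r - band_px.  The per-pixel mean of each
    region is compared: pass iff edge/interior >= min_ratio.  A zero
    interior with a positive rim passes (infinite contrast).  Filled discs
    (ratio ~1) fail — the multilamellar-like case with too much
    fluorescence inside the vesicle.
    """
    if band_px < 1:
        raise ValueError("band_px must be >= 1")
    if not circle.bbox_inside(image.shape):
        return False, {"reason": "edge-touching"}
    rim = annulus_mask(image.shape, circle.cx, circle.cy, circle.r, band_px)
    interior = disc_mask(image.shape, circle.cx, circle.cy, circle.r - band_px)
    if not rim.any():
        return False, {"reason": "empty-rim"}
    edge_mean = float(np.asarray(image, dtype=float)[rim].mean())
    interior_mean = (
        float(np.asarray(image, dtype=float)[interior].mean())
        if interior.any()
        else 0.0
    )
    metrics = {
        "edge_intensity_per_px": edge_mean,
        "interior_intensity_per_px": interior_mean,
    }
    if interior_mean <= 0:
        passed = edge_mean > 0
    else:
        passed = edge_mean / interior_mean >= min_ratio
    if not passed:
        metrics["reason"] = "low-edge-contrast"
    return passed, metrics


def group_circles(
    detections: list[CircleDetection],
    center_tolerance: float = DEFAULT_CENTER_TOLERANCE_PX,
) -> list[VesicleEntity]:
    """Greedy z-ascending grouping of circles into vesicle entities.

    Sections are processed in ascending z.  Within one section, circles and
    open entities are matched globally nearest-first (so the result does not
    depend on detection order within a section); a circle joins the entity
    whose most recent center is within ``center_tolerance``, otherwise it
    seeds a new entity.  Every circle ends up in exactly one entity.
    """
    entities: list[VesicleEntity] = []
    by_z: dict[int, list[CircleDetection]] = {}
    for det in detections:
        by_z.setdefault(det.z_index, []).append(det)

    for z in sorted(by_z):
        circles = by_z[z]
        # candidate (distance, circle, entity) pairs within tolerance
        pairs = []
        for ci, c in enumerate(circles):
            for ei, e in enumerate(entities):
                ex, ey = e.last_center()
                d = float(np.hypot(c.cx - ex, c.cy - ey))
                if d <= center_tolerance:
                    # tie-break on coordinates for order independence
                    pairs.append((d, c.cx, c.cy, e.last_center(), ci, ei))
        pairs.sort()
        used_c: set[int] = set()
        used_e: set[int] = set()
        for d, _, _, _, ci, ei in pairs:
            if ci in used_c or ei in used_e:
                continue
            entities[ei].sections.append(circles[ci])
            used_c.add(ci)
            used_e.add(ei)
        leftovers = sorted(
            (c for ci, c in enumerate(circles) if ci not in used_c),
            key=lambda c: (c.cx, c.cy, c.r),
        )
        for c in leftovers:
            entities.append(VesicleEntity(vesicle_id=len(entities), sections=[c]))
    return entities


def filter_min_sections(
    entities: list[VesicleEntity], min_sections: int = DEFAULT_MIN_SECTIONS
) -> list[VesicleEntity]:
    """Reject entities with too few sections to form an intact 3-D GUV.

    With the default ``min_sections=3``, groups with only one or two image
    sections are filtered out.
    """
    if min_sections < 1:
        raise ValueError("min_sections must be >= 1")
    for e in entities:
        if e.accepted and e.n_sections < min_sections:
            e.status = "rejected:too-few-sections"
    return [e for e in entities if e.accepted]


def exclude_edge_entities(
    entities: list[VesicleEntity], image_shape: tuple[int, int]
) -> list[VesicleEntity]:
    """Reject entities any of whose section circles touch the image edge."""
    for e in entities:
        if e.accepted and any(not c.bbox_inside(image_shape) for c in e.sections):
            e.status = "rejected:edge-touching"
    return [e for e in entities if e.accepted]


def entities_table(entities: list[VesicleEntity]) -> pd.DataFrame:
    """Summarize entities as the CSV-ready table the pipeline writes."""
    rows = []
    for e in entities:
        zs = [c.z_index for c in e.sections]
        status, _, reason = e.status.partition(":")
        rows.append(
            {
                "vesicle_id": e.vesicle_id,
                "n_sections": e.n_sections,
                "z_min": min(zs),
                "z_max": max(zs),
                "mean_r_px": e.mean_radius,
                "status": status,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)
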