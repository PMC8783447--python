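"""Versioned analysis configuration: one schema, YAML round-trip.

Every user parameter of the three programs lives here with its default;
each run's manifest embeds the fully resolved configuration so results
are reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

CONFIG_SCHEMA_VERSION = 1


@dataclass
class AnalysisConfig:
    # segmentation
    radius_range_px: tuple[int, int] = (20, 120)
    cht_sensitivity: float = 0.5
    radius_step_px: int = 1
    use_mask: bool = True
    # grouping and selection
    center_tolerance_px: float = 10.0
    min_sections: int = 3
    band_px: float = 3.0
    min_edge_ratio: float = 1.5
    # intensity analysis
    inward_px: int = 3
    background: str | float = "auto"  # "auto" or a fixed per-px level
    # contour phase statistic
    contour_n_segments: int = 36
    contour_delta_r_px: float = 3.0
    contour_percentile: float = 20.0
    contour_p_percent: float = 20.0
    decision_fraction: float = 0.40
    # CNN models
    selection_model_path: str | None = None
    state_model_path: str | None = None
    patch_margin: float = 1.2
    # channels: A detects geometry, B is measured
    channel_a: int = 0
    channel_b: int = 1
    interleaving: str = "z-major"
    seed: int = 0
    schema_version: int = CONFIG_SCHEMA_VERSION

    def to_dict(self) -> dict:
        d = asdict(self)
        d["radius_range_px"] = list(self.radius_range_px)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "radius_range_px" in data:
            data = dict(data)
            data["radius_range_px"] = tuple(data["radius_range_px"])
        return cls(**data)
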