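"""End-to-end programs 1-3: segmentation through reports and overlays.

All three programs share the front end — per-section triangle masking, CHT
circle detection, grouping into 3-D entities, minimum-section and edge
filtering — and differ in who selects vesicles and who decides the phase
state:

* program 1: edge-contrast selection, contour-statistic state decision,
  and the intensity analyses (binding / droplet) — all pixel computation;
* program 2: CNN selection (4-class filter), contour-statistic state;
* program 3: CNN selection and CNN state decision on background-zeroed
  patches.

Each run returns a :class:`PipelineResult` whose report embeds the fully
resolved configuration; with an output directory, CSV tables, PNG overlays
and a YAML run manifest are written.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assemble import (
    VesicleEntity,
    edge_contrast_filter,
    entities_table,
    exclude_edge_entities,
    filter_min_sections,
    group_circles,
)
from .classify import PatchClassifier, classify, cnn_selection_filter, prepare_patch
from .config import AnalysisConfig
from .contour import (
    PhaseDecision,
    contour_profile,
    domain_levels,
    section_state,
    vesicle_state,
)
from .intensity import (
    droplet_interior_intensity,
    estimate_background,
    measure_entity_binding,
)
from .segment import CircleDetection, detect_circles
from .stacks import ImageStack

logger = logging.getLogger("guvstack")

#: Overlay colors: selection classes C1-C4 plus edge-touching rejection.
CLASS_COLORS = {"C1": "cyan", "C2": "green", "C3": "blue", "C4": "magenta"}
EDGE_COLOR = "red"
#: Phase-state overlay colors.
STATE_COLORS = {"uniform": "blue", "separated": "yellow"}


@dataclass
class PipelineResult:
    entities: list[VesicleEntity]
    report: pd.DataFrame
    manifest: dict
    decisions: list[PhaseDecision] = field(default_factory=list)


# ---------------------------------------------------------------------------
# shared front end


def detect_stack_circles(stack: ImageStack, cfg: AnalysisConfig) -> list[CircleDetection]:
    """CHT detection on every section of the detection channel."""
    detections: list[CircleDetection] = []
    for z in range(stack.n_sections):
        found = detect_circles(
            stack[z],
            radius_range=cfg.radius_range_px,
            sensitivity=cfg.cht_sensitivity,
            z_index=z,
            use_mask=cfg.use_mask,
            radius_step=cfg.radius_step_px,
        )
        logger.debug("z=%d: %d circles", z, len(found))
        detections.extend(found)
    return detections


def _assemble(
    stack: ImageStack,
    detections: list[CircleDetection],
    cfg: AnalysisConfig,
    use_edge_contrast: bool,
) -> list[VesicleEntity]:
    if use_edge_contrast:
        kept = []
        for det in detections:
            passed, metrics = edge_contrast_filter(
                stack[det.z_index], det, cfg.band_px, cfg.min_edge_ratio
            )
            if passed:
                kept.append(det)
            else:
                logger.debug("z=%d circle (%.0f, %.0f) rejected: %s",
                             det.z_index, det.cx, det.cy, metrics.get("reason"))
        detections = kept
    entities = group_circles(detections, cfg.center_tolerance_px)
    entities = filter_min_sections(entities, cfg.min_sections)
    entities = exclude_edge_entities(entities, stack.frame_shape)
    return entities


def _background(image: np.ndarray, cfg: AnalysisConfig) -> float:
    if cfg.background == "auto":
        return estimate_background(image)
    return float(cfg.background)


def _manifest(cfg: AnalysisConfig, program: str, mode: str) -> dict:
    return {
        "program": program,
        "mode": mode,
        "guvstack_version": __version__,
        "config": cfg.to_dict(),
    }


# ---------------------------------------------------------------------------
# program bodies


def run_program1(
    stacks: list[ImageStack],
    cfg: AnalysisConfig | None = None,
    mode: str = "binding",
    outdir=None,
) -> PipelineResult:
    """Pixel-computation pipeline: mask -> CHT -> contrast filter -> group.

    ``mode`` selects the analysis performed on accepted entities:
    ``binding`` (membrane channel-B intensity), ``droplet`` (interior
    intensity) or ``phase`` (contour-statistic state decision).
    """
    cfg = cfg or AnalysisConfig()
    stack_a = stacks[cfg.channel_a]
    detections = detect_stack_circles(stack_a, cfg)
    if not detections:
        warnings.warn("no circles detected; returning an empty report")
        return PipelineResult([], pd.DataFrame(), _manifest(cfg, "program1", mode))
    entities = _assemble(stack_a, detections, cfg, use_edge_contrast=True)
    result = _analyze(stacks, entities, cfg, mode, state_model=None)
    result.manifest.update(_manifest(cfg, "program1", mode))
    if outdir is not None:
        _write_outputs(result, stack_a, cfg, outdir, mode)
    return result


def run_program2(
    stacks: list[ImageStack],
    cfg: AnalysisConfig | None = None,
    selection_model: PatchClassifier | None = None,
    mode: str = "phase",
    outdir=None,
) -> PipelineResult:
    """As program 1, with the per-circle filter replaced by the 4-class CNN."""
    cfg = cfg or AnalysisConfig()
    selection_model = _load_model(selection_model, cfg.selection_model_path)
    stack_a = stacks[cfg.channel_a]
    detections = detect_stack_circles(stack_a, cfg)
    if not detections:
        warnings.warn("no circles detected; returning an empty report")
        return PipelineResult([], pd.DataFrame(), _manifest(cfg, "program2", mode))
    entities = group_circles(detections, cfg.center_tolerance_px)
    entities = cnn_selection_filter(
        entities, stack_a, selection_model, cfg.patch_margin, cfg.min_sections
    )
    entities = exclude_edge_entities(entities, stack_a.frame_shape)
    result = _analyze(stacks, entities, cfg, mode, state_model=None)
    result.manifest.update(_manifest(cfg, "program2", mode))
    if outdir is not None:
        _write_outputs(result, stack_a, cfg, outdir, mode)
    return result


def run_program3(
    stacks: list[ImageStack],
    cfg: AnalysisConfig | None = None,
    selection_model: PatchClassifier | None = None,
    state_model: PatchClassifier | None = None,
    outdir=None,
) -> PipelineResult:
    """CNN selection and CNN state decision (phase mode only)."""
    cfg = cfg or AnalysisConfig()
    selection_model = _load_model(selection_model, cfg.selection_model_path)
    state_model = _load_model(state_model, cfg.state_model_path)
    stack_a = stacks[cfg.channel_a]
    detections = detect_stack_circles(stack_a, cfg)
    if not detections:
        warnings.warn("no circles detected; returning an empty report")
        return PipelineResult([], pd.DataFrame(), _manifest(cfg, "program3", "phase"))
    entities = group_circles(detections, cfg.center_tolerance_px)
    entities = cnn_selection_filter(
        entities, stack_a, selection_model, cfg.patch_margin, cfg.min_sections
    )
    entities = exclude_edge_entities(entities, stack_a.frame_shape)
    result = _analyze(stacks, entities, cfg, "phase", state_model=state_model)
    result.manifest.update(_manifest(cfg, "program3", "phase"))
    if outdir is not None:
        _write_outputs(result, stack_a, cfg, outdir, "phase")
    return result


def _load_model(model, path):
    if model is not None:
        return model
    if path is None:
        raise ValueError("a CNN model is required but neither object nor path given")
    if not Path(path).with_suffix(".npz").exists():
        raise FileNotFoundError(f"model checkpoint not found: {path}")
    return PatchClassifier.load(path)


# ---------------------------------------------------------------------------
# per-entity analyses


def _analyze(
    stacks: list[ImageStack],
    entities: list[VesicleEntity],
    cfg: AnalysisConfig,
    mode: str,
    state_model: PatchClassifier | None,
) -> PipelineResult:
    if mode == "binding":
        report = _binding_report(stacks, entities, cfg)
        decisions = []
    elif mode == "droplet":
        report = _droplet_report(stacks, entities, cfg)
        decisions = []
    elif mode == "phase":
        report, decisions = _phase_report(stacks, entities, cfg, state_model)
    else:
        raise ValueError(f"unknown analysis mode: {mode!r}")
    return PipelineResult(entities, report, {}, decisions)


def _binding_report(stacks, entities, cfg) -> pd.DataFrame:
    stack_b = stacks[cfg.channel_b]
    backgrounds = [_background(stack_b[z], cfg) for z in range(stack_b.n_sections)]
    rows = []
    for e in entities:
        res = measure_entity_binding(stack_b, e, cfg.inward_px, backgrounds)
        rows.append(
            {
                "vesicle_id": e.vesicle_id,
                "n_sections": e.n_sections,
                "mean_r_px": e.mean_radius,
                "total_net_intensity": sum(t for t, _, _ in res.per_section),
                "net_per_px": res.vesicle_mean_per_px,
                "pixel_count": sum(n for _, _, n in res.per_section),
            }
        )
    return pd.DataFrame(rows)


def _droplet_report(stacks, entities, cfg) -> pd.DataFrame:
    stack_b = stacks[cfg.channel_b]
    rows = []
    for e in entities:
        nets, counts = [], []
        for circ in e.sections:
            img = stack_b[circ.z_index]
            net, n = droplet_interior_intensity(img, circ, _background(img, cfg))
            nets.append(net)
            counts.append(n)
        weighted = float(np.average(nets, weights=counts))
        rows.append(
            {
                "droplet_id": e.vesicle_id,
                "n_sections": e.n_sections,
                "mean_r_px": e.mean_radius,
                "net_per_px": weighted,
                "pixel_count": int(np.sum(counts)),
            }
        )
    return pd.DataFrame(rows)


def _phase_report(stacks, entities, cfg, state_model) -> tuple[pd.DataFrame, list]:
    stack = stacks[cfg.channel_b] if len(stacks) > cfg.channel_b else stacks[cfg.channel_a]
    rows, decisions = [], []
    for e in entities:
        states, levels, probs = [], [], []
        for circ in e.sections:
            img = stack[circ.z_index]
            if state_model is not None:
                patch = prepare_patch(img, circ, cfg.patch_margin, zero_bg=True)
                cls, p = classify(state_model, patch)
                states.append("separated" if cls == "C2" else "uniform")
                probs.append(p)
                levels.append((float("nan"),) * 3)
            else:
                # measure with the annulus centered on the detected ring
                # crest: (r - dr, r] applied at radius r_hat + dr/2 brackets
                # the blurred membrane peak instead of sampling its inner tail
                from dataclasses import replace

                crest = replace(circ, r=circ.r + cfg.contour_delta_r_px / 2.0)
                if not crest.bbox_inside(img.shape):
                    crest = circ  # expanded annulus would leave the frame
                prof = contour_profile(
                    img,
                    crest,
                    cfg.contour_n_segments,
                    cfg.contour_delta_r_px,
                    _background(img, cfg),
                )
                levels.append(domain_levels(prof, cfg.contour_percentile))
                states.append(
                    section_state(prof, cfg.contour_percentile, cfg.contour_p_percent)
                )
        decision = vesicle_state(states, cfg.decision_fraction, e.vesicle_id, levels)
        decisions.append(decision)
        row = {
            "vesicle_id": e.vesicle_id,
            "n_sections": e.n_sections,
            "mean_r_px": e.mean_radius,
            "fraction_separated": decision.fraction_separated,
            "state": decision.vesicle_state,
            "high": float(np.nanmean([lv[0] for lv in levels])),
            "low": float(np.nanmean([lv[1] for lv in levels])),
        }
        if probs:
            row["mean_prob_separated"] = float(np.mean([p[1] for p in probs]))
        rows.append(row)
    return pd.DataFrame(rows), decisions


# ---------------------------------------------------------------------------
# outputs


def _write_outputs(result: PipelineResult, stack_a: ImageStack, cfg, outdir, mode):
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.report.to_csv(outdir / "report.csv", index=False)
    entities_table(result.entities).to_csv(outdir / "entities.csv", index=False)
    (outdir / "run_manifest.yaml").write_text(yaml.safe_dump(result.manifest))
    if mode == "phase" and result.decisions:
        z_mid = stack_a.n_sections // 2
        states = {d.vesicle_id: d.vesicle_state for d in result.decisions}
        save_overlay(
            stack_a[z_mid],
            result.entities,
            outdir / f"overlay_z{z_mid:03d}.png",
            state_by_id=states,
        )


def save_overlay(
    image: np.ndarray,
    entities: list[VesicleEntity],
    path,
    state_by_id: dict | None = None,
    class_by_id: dict | None = None,
) -> None:
    """Color-coded QC overlay.

    Phase mode circles uniform vesicles in blue and separated in yellow;
    selection mode uses cyan/green/blue/magenta for C1-C4 and red for
    edge-touching rejections.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(image, cmap="gray")
    for e in entities:
        color = "white"
        if e.status == "rejected:edge-touching":
            color = EDGE_COLOR
        elif class_by_id and e.vesicle_id in class_by_id:
            color = CLASS_COLORS.get(class_by_id[e.vesicle_id], "white")
        elif state_by_id and e.vesicle_id in state_by_id:
            color = STATE_COLORS.get(state_by_id[e.vesicle_id], "white")
        for circ in e.sections:
            ax.add_patch(
                plt.Circle((circ.cx, circ.cy), circ.r, fill=False, color=color, lw=0.8)
            )
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
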