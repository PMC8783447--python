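"""Self-validation benchmarks on simulated ground truth.

Because the simulator provides exact annotations, every stage of the
pipeline can be scored against truth without external data: segmentation
recall on isolated rings, phase-state accuracy of the contour statistic and
of the state CNN on populations of virtual vesicles, recovery of a known
before/after binding contrast, and the virtual-training experiment for the
2-class state classifier.  The functions here are deliberately small
drivers around the public package surface; each returns plain numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .classify import PatchClassifier, augment, prepare_patch
from .config import AnalysisConfig
from .contour import SEPARATED, contour_profile, section_state, vesicle_state
from .intensity import condition_summary
from .pipeline import run_program1
from .segment import detect_circles
from .simulate import (
    DomainSphere,
    Vesicle,
    VirtualScene,
    generate_training_set,
    render_section,
    render_zstack,
)
from .stacks import ImageStack


# ---------------------------------------------------------------------------
# virtual-training experiment (2-class state CNN)


def virtual_training_run(
    n_per_class: int = 5000,
    n_val_per_class: int = 750,
    seed: int = 0,
    augment_multiplier: int = 2,
) -> tuple[float, PatchClassifier]:
    """Train the state CNN on simulator patches; return held-out accuracy.

    Generates background-thresholded homogeneous/separated patch sets,
    augments the training set by scaling and position shifting, trains with
    the fixed SGDM recipe, and evaluates on a disjoint validation draw.
    """
    rng = np.random.default_rng(seed)
    train_set = generate_training_set("state-2class", n_per_class, rng=rng)
    val_set = generate_training_set("state-2class", n_val_per_class, rng=rng)
    if augment_multiplier > 1:
        train_set = augment(
            train_set,
            scale_range=(0.9, 1.1),
            shift_range=(-3.0, 3.0),
            multiplier=augment_multiplier,
            rng=rng,
        )
    clf = PatchClassifier(kind="state", random_state=seed)
    clf.fit(train_set.patches, train_set.labels, val_set.patches, val_set.labels)
    return clf.val_accuracy_, clf


# ---------------------------------------------------------------------------
# segmentation recall


def segmentation_recall(
    n_circles: int = 50,
    seed: int = 0,
    radius_range: tuple[int, int] = (20, 120),
) -> dict:
    """Detect isolated noiseless rendered rings across the radius range.

    Returns recall plus the worst center/radius errors (px) over all hits.
    """
    rng = np.random.default_rng(seed)
    hits, center_errs, radius_errs = 0, [], []
    for _ in range(n_circles):
        r_px = float(rng.uniform(*radius_range))
        side = int(2 * r_px + 40)
        cx = side / 2 + rng.uniform(-6, 6)
        cy = side / 2 + rng.uniform(-6, 6)
        scene = VirtualScene(
            vesicles=[Vesicle((cx, cy, r_px), r_px, 800.0)],
            field_of_view_um=float(side),
            frame_px=side,
            psf_sigma_xy_px=1.5,
            background_level=30.0,
        )
        img = render_section(scene, r_px, noiseless=True)
        found = detect_circles(img, radius_range)
        if not found:
            continue
        det = found[0]
        ce = math.hypot(det.cx - cx, det.cy - cy)
        re = abs(det.r - r_px)
        if ce <= 2.0 and re <= 2.0:
            hits += 1
        center_errs.append(ce)
        radius_errs.append(re)
    return {
        "recall": hits / n_circles,
        "max_center_err_px": max(center_errs, default=float("nan")),
        "max_radius_err_px": max(radius_errs, default=float("nan")),
    }


# ---------------------------------------------------------------------------
# phase-state accuracy on vesicle populations


@dataclass
class _VesicleCase:
    scene: VirtualScene
    separated: bool


def _sample_case(rng: np.random.Generator, separated: bool) -> _VesicleCase:
    """One single-vesicle mini-scene at 1 µm/px with an equatorial-belt cap.

    Separated vesicles carry one domain sphere centered on the shell within
    40 degrees of the equator, with 3-D cap half-angle in [40, 110] degrees,
    so most analyzable sections cross the domain with a clear arc.
    """
    r = float(rng.uniform(24, 38))
    side = int(2 * r + 24)
    cx = side / 2 + rng.uniform(-2, 2)
    cy = side / 2 + rng.uniform(-2, 2)
    z0 = r + 1.0
    membrane = float(rng.uniform(400, 800))
    vesicle = Vesicle((cx, cy, z0), r, membrane)
    domains = []
    if separated:
        psi = math.radians(rng.uniform(40, 110))
        polar = math.radians(rng.uniform(60, 120))
        azim = rng.uniform(0, 2 * math.pi)
        u = (
            math.sin(polar) * math.cos(azim),
            math.sin(polar) * math.sin(azim),
            math.cos(polar),
        )
        domains.append(
            DomainSphere(
                0,
                (cx + r * u[0], cy + r * u[1], z0 + r * u[2]),
                2.0 * r * math.sin(psi / 2.0),
                float(rng.uniform(0.15, 0.45)) * membrane,
            )
        )
    scene = VirtualScene(
        vesicles=[vesicle],
        domains=domains,
        field_of_view_um=float(side),
        frame_px=side,
        z_spacing_um=max(2.0, r / 6.0),
        psf_sigma_xy_px=1.5,
        background_level=30.0,
        noise_sigma=0.05 * membrane,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )
    return _VesicleCase(scene, separated)


def phase_state_accuracy(
    n_vesicles: int = 200,
    seed: int = 0,
    state_classifier: PatchClassifier | None = None,
    min_section_radius_px: float = 20.0,
    cfg: AnalysisConfig | None = None,
) -> dict:
    """Vesicle-state accuracy of the contour statistic and/or the state CNN.

    Renders ``n_vesicles`` single-vesicle stacks (half homogeneous, half
    domain-separated, noise 5% of the membrane level) and scores each
    method's per-vesicle decision against ground truth.  Geometry comes
    from the annotation table so the comparison isolates state
    determination from segmentation.

    The default discontinuity band is p = 35% here rather than the package
    default 20%: the simulated reporter partitions strongly (the dim domain
    carries at most 45% of the bright level), and the method prescribes a
    higher p for strongly partitioned reporters so that noise swings on
    homogeneous contours stay inside the dead band.
    """
    cfg = cfg or AnalysisConfig(contour_p_percent=35.0)
    rng = np.random.default_rng(seed)
    cases = [_sample_case(rng, i % 2 == 1) for i in range(n_vesicles)]
    contour_hits = 0
    cnn_hits = 0
    per_section_total = 0
    per_section_correct = 0
    for case in cases:
        stack, ann = render_zstack(case.scene)
        rows = ann[ann.r_px >= min_section_radius_px]
        contour_states, cnn_states = [], []
        for _, row in rows.iterrows():
            img = stack[int(row.z_index)]
            from .intensity import estimate_background
            from .segment import CircleDetection

            circ = CircleDetection(
                z_index=int(row.z_index), cx=row.cx_px, cy=row.cy_px, r=row.r_px
            )
            crest = replace(circ, r=circ.r + cfg.contour_delta_r_px / 2.0)
            bg = estimate_background(img)
            try:
                prof = contour_profile(
                    img, crest, cfg.contour_n_segments, cfg.contour_delta_r_px, bg
                )
                st = section_state(prof, cfg.contour_percentile, cfg.contour_p_percent)
            except ValueError:
                st = "uniform"
            contour_states.append(st)
            per_section_total += 1
            per_section_correct += (st == SEPARATED) == (row.phase_label == "separated")
            if state_classifier is not None:
                patch = prepare_patch(img, circ, cfg.patch_margin, zero_bg=True)
                pred = state_classifier.predict(patch)
                cnn_states.append(SEPARATED if pred == "C2" else "uniform")
        truth = case.separated
        if contour_states:
            decision = vesicle_state(contour_states, cfg.decision_fraction)
            contour_hits += (decision.vesicle_state == SEPARATED) == truth
        if state_classifier is not None and cnn_states:
            decision = vesicle_state(cnn_states, cfg.decision_fraction)
            cnn_hits += (decision.vesicle_state == SEPARATED) == truth
    out = {
        "contour_accuracy": contour_hits / n_vesicles,
        "section_accuracy": per_section_correct / max(per_section_total, 1),
    }
    if state_classifier is not None:
        out["cnn_accuracy"] = cnn_hits / n_vesicles
    return out


# ---------------------------------------------------------------------------
# binding-contrast recovery


def binding_contrast_recovery(
    seed: int = 0,
    ratio: float = 20.0,
    n_stacks_per_condition: int = 3,
    n_vesicles: int = 3,
) -> dict:
    """Recover a known before/after channel-B contrast with program 1.

    Simulates paired conditions whose true membrane channel-B levels stand
    in a ``ratio`` : 1 relation (plus noise) and reports the ratio of the
    recovered condition means.
    """
    rng = np.random.default_rng(seed)
    cfg = AnalysisConfig(radius_range_px=(20, 40), background="auto")
    level_after = 25.0
    level_before = level_after * ratio
    cond_means = {}
    for cond, level in (("before", level_before), ("after", level_after)):
        stack_means = []
        for _ in range(n_stacks_per_condition):
            vesicles = []
            positions = [(48.0, 48.0), (144.0, 48.0), (96.0, 144.0)][:n_vesicles]
            for px, py in positions:
                vesicles.append(
                    Vesicle(
                        (px + rng.uniform(-6, 6), py + rng.uniform(-6, 6), 30.0),
                        float(rng.uniform(24, 30)),
                        600.0,
                    )
                )
            scene = VirtualScene(
                vesicles=vesicles,
                field_of_view_um=192.0,
                frame_px=192,
                z_spacing_um=4.0,
                psf_sigma_xy_px=1.2,
                background_level=30.0,
                noise_sigma=12.0,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
            )
            stack_a, ann = render_zstack(scene)
            # channel B: uniform membrane bands at the true geometry over a
            # flat background, plus read noise
            bg_b = 40.0
            sections = np.full(stack_a.sections.shape, bg_b)
            yy, xx = np.mgrid[0:192, 0:192]
            for _, row in ann.iterrows():
                band = (
                    np.hypot(xx - row.cx_px, yy - row.cy_px) > row.r_px - 6
                ) & (np.hypot(xx - row.cx_px, yy - row.cy_px) <= row.r_px + 2)
                sections[int(row.z_index)][band] = bg_b + level
            sections = sections + rng.normal(0, 2.0, sections.shape)
            stack_b = ImageStack(sections)
            result = run_program1([stack_a, stack_b], cfg, mode="binding")
            if len(result.report):
                stack_means.append(float(result.report.net_per_px.mean()))
        mean, sd = condition_summary(stack_means)
        cond_means[cond] = mean
    recovered = cond_means["before"] / cond_means["after"]
    return {
        "recovered_ratio": recovered,
        "true_ratio": ratio,
        "relative_error": abs(recovered - ratio) / ratio,
    }
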