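"""Virtual confocal GUV scenes: ground truth, rendering, training patches.

A virtual scene describes vesicles as perfect spherical shells in physical
(µm) coordinates; phase-separated membrane domains are defined by
overlapping a secondary sphere with the shell — the shell surface inside
the domain sphere carries a different reporter level.  A z-section renders
the exact geometric cross-section (a 1-px-wide ring of radius
sqrt(R^2 - (z - z0)^2), a domain arc where the ring lies inside a domain
sphere, an interior disc), then applies an in-plane Gaussian PSF and
additive Gaussian noise to emulate a confocal image.  Because the ground
truth is analytic, every render comes with exact annotations: per-section
center, ring radius and phase label.

The same machinery produces labeled 50x50 patches for the two CNNs: the
4-class vesicle-selection filter (unilamellar / multilamellar / overlapping
/ hazy) and the 2-class phase-state classifier (homogeneous / separated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import distance_grid
from .segment import triangular_threshold
from .stacks import (
    DEFAULT_FIELD_OF_VIEW_UM,
    DEFAULT_FRAME_PX,
    DEFAULT_Z_SPACING_UM,
    ImageStack,
)

PATCH_SIZE = 50

SELECTION_CLASSES = ["C1", "C2", "C3", "C4"]
STATE_CLASSES = ["C1", "C2"]  # homogeneous, domain-separated


# ---------------------------------------------------------------------------
# scene description


@dataclass
class Vesicle:
    """A perfectly globular vesicle: spherical shell + optional interior."""

    center_um: tuple[float, float, float]  # (x, y, z)
    radius_um: float
    membrane_level: float
    interior_level: float = 0.0


@dataclass
class DomainSphere:
    """Secondary sphere defining a membrane domain on its parent shell."""

    parent_index: int
    center_um: tuple[float, float, float]
    radius_um: float
    membrane_level: float


@dataclass
class VirtualScene:
    """Ground-truth scene plus render parameters.

    Labels are derivable from the scene alone; rendering is only needed to
    produce images.
    """

    vesicles: list[Vesicle] = field(default_factory=list)
    domains: list[DomainSphere] = field(default_factory=list)
    field_of_view_um: float = DEFAULT_FIELD_OF_VIEW_UM
    frame_px: int = DEFAULT_FRAME_PX
    z_spacing_um: float = DEFAULT_Z_SPACING_UM
    psf_sigma_xy_px: float = 1.5
    background_level: float = 30.0
    noise_sigma: float = 0.0
    rng_seed: int = 0

    @property
    def pixel_size_um(self) -> float:
        return self.field_of_view_um / self.frame_px

    def __post_init__(self) -> None:
        if self.field_of_view_um <= 0 or self.frame_px <= 0:
            raise ValueError("field of view and frame size must be positive")
        if self.z_spacing_um <= 0:
            raise ValueError("z_spacing must be positive")
        for v in self.vesicles:
            if v.radius_um <= 0:
                raise ValueError("vesicle radius must be positive")
        for d in self.domains:
            if not 0 <= d.parent_index < len(self.vesicles):
                raise ValueError("domain parent index out of range")
            if d.radius_um <= 0:
                raise ValueError("domain sphere radius must be positive")


@dataclass
class SceneParams:
    """Sampling ranges for randomized scenes.  All ranges are inclusive."""

    n_vesicles: tuple[int, int] = (4, 8)
    radius_um: tuple[float, float] = (5.0, 12.0)
    membrane_level: tuple[float, float] = (400.0, 800.0)
    interior_level: tuple[float, float] = (0.0, 20.0)
    domain_probability: float = 0.5
    #: domain-sphere radius as a fraction of the parent radius; the sphere is
    #: centered on the shell surface, so fraction f cuts a cap of half-angle
    #: 2*arcsin(f/2) out of the membrane
    domain_radius_frac: tuple[float, float] = (0.5, 1.2)
    domain_level_frac: tuple[float, float] = (0.15, 0.45)
    background_level: tuple[float, float] = (20.0, 50.0)
    #: additive Gaussian noise sigma as a fraction of the membrane level
    noise_sigma_frac: float = 0.05
    psf_sigma_xy_px: tuple[float, float] = (1.2, 2.0)
    field_of_view_um: float = DEFAULT_FIELD_OF_VIEW_UM
    frame_px: int = DEFAULT_FRAME_PX
    z_spacing_um: float = DEFAULT_Z_SPACING_UM
    #: minimum center separation between vesicles, in units of summed radii
    min_separation: float = 1.1

    def validate(self) -> None:
        for name in (
            "n_vesicles",
            "radius_um",
            "membrane_level",
            "interior_level",
            "domain_radius_frac",
            "domain_level_frac",
            "background_level",
            "psf_sigma_xy_px",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if not 0.0 <= self.domain_probability <= 1.0:
            raise ValueError("domain_probability must lie in [0, 1]")


def _uniform(rng: np.random.Generator, rang: tuple[float, float]) -> float:
    lo, hi = rang
    return float(lo) if lo == hi else float(rng.uniform(lo, hi))


def sample_scene(params: SceneParams, rng: np.random.Generator) -> VirtualScene:
    """Draw one randomized scene; every quantity lies within its range.

    Vesicle centers are rejection-sampled so that no two vesicles are closer
    than ``min_separation`` times the sum of their radii in the xy plane.
    """
    params.validate()
    n = int(rng.integers(params.n_vesicles[0], params.n_vesicles[1] + 1))
    fov = params.field_of_view_um
    vesicles: list[Vesicle] = []
    for _ in range(n):
        r = _uniform(rng, params.radius_um)
        for _attempt in range(2000):
            x = rng.uniform(r, fov - r)
            y = rng.uniform(r, fov - r)
            ok = all(
                math.hypot(x - v.center_um[0], y - v.center_um[1])
                >= params.min_separation * (r + v.radius_um)
                for v in vesicles
            )
            if ok:
                break
        else:
            raise RuntimeError(
                "could not place all vesicles; enlarge the field of view or "
                "reduce n_vesicles/min_separation"
            )
        z0 = r + rng.uniform(0.0, params.z_spacing_um)
        vesicles.append(
            Vesicle(
                center_um=(float(x), float(y), float(z0)),
                radius_um=r,
                membrane_level=_uniform(rng, params.membrane_level),
                interior_level=_uniform(rng, params.interior_level),
            )
        )
    domains: list[DomainSphere] = []
    for i, v in enumerate(vesicles):
        if rng.uniform() < params.domain_probability:
            frac = _uniform(rng, params.domain_radius_frac)
            # domain sphere centered on the shell at a random surface point
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            cx, cy, cz = v.center_um
            center = (
                cx + v.radius_um * u[0],
                cy + v.radius_um * u[1],
                cz + v.radius_um * u[2],
            )
            domains.append(
                DomainSphere(
                    parent_index=i,
                    center_um=center,
                    radius_um=frac * v.radius_um,
                    membrane_level=_uniform(rng, params.domain_level_frac)
                    * v.membrane_level,
                )
            )
    mem_mean = float(np.mean([v.membrane_level for v in vesicles])) if vesicles else 0.0
    return VirtualScene(
        vesicles=vesicles,
        domains=domains,
        field_of_view_um=fov,
        frame_px=params.frame_px,
        z_spacing_um=params.z_spacing_um,
        psf_sigma_xy_px=_uniform(rng, params.psf_sigma_xy_px),
        background_level=_uniform(rng, params.background_level),
        noise_sigma=params.noise_sigma_frac * mem_mean,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# rendering


def section_ring_radius_um(vesicle: Vesicle, z_um: float) -> float | None:
    """True ring radius of a vesicle's cross-section at height z, or None."""
    dz = z_um - vesicle.center_um[2]
    if abs(dz) > vesicle.radius_um:
        return None
    return math.sqrt(max(vesicle.radius_um**2 - dz**2, 0.0))


def section_phase_label(scene: VirtualScene, vesicle_index: int, z_um: float) -> str:
    """Ground-truth phase label of one vesicle's section.

    ``separated`` iff the section's ring intersects a domain sphere of that
    vesicle over a nonzero arc — i.e. the closest ring point lies strictly
    inside the sphere.
    """
    v = scene.vesicles[vesicle_index]
    rho = section_ring_radius_um(v, z_um)
    if rho is None or rho == 0.0:
        return "uniform"
    for d in scene.domains:
        if d.parent_index != vesicle_index:
            continue
        q = math.hypot(
            d.center_um[0] - v.center_um[0], d.center_um[1] - v.center_um[1]
        )
        min_d2 = (q - rho) ** 2 + (z_um - d.center_um[2]) ** 2
        if min_d2 < d.radius_um**2:
            return "separated"
    return "uniform"


def render_section(
    scene: VirtualScene,
    z_um: float,
    noiseless: bool = False,
    apply_psf: bool = True,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one z-section of the scene as a float image.

    The exact geometric cross-section is drawn first (ring at the membrane
    level, domain arcs at their domain level, interior disc, background
    elsewhere), then convolved with the in-plane Gaussian PSF, then
    additive Gaussian noise is applied unless ``noiseless``.
    """
    ps = scene.pixel_size_um
    shape = (scene.frame_px, scene.frame_px)
    img = np.full(shape, scene.background_level, dtype=float)
    for i, v in enumerate(scene.vesicles):
        rho = section_ring_radius_um(v, z_um)
        if rho is None:
            continue
        cx_px, cy_px = v.center_um[0] / ps, v.center_um[1] / ps
        rho_px = rho / ps
        d = distance_grid(shape, cx_px, cy_px)
        interior = d <= rho_px - 0.5
        if interior.any():
            img[interior] = np.maximum(img[interior], v.interior_level)
        ring = np.abs(d - rho_px) <= 0.5
        if not ring.any():
            continue
        img[ring] = np.maximum(img[ring], v.membrane_level)
        for dom in scene.domains:
            if dom.parent_index != i:
                continue
            yy, xx = np.nonzero(ring)
            px_um = xx * ps
            py_um = yy * ps
            inside = (
                (px_um - dom.center_um[0]) ** 2
                + (py_um - dom.center_um[1]) ** 2
                + (z_um - dom.center_um[2]) ** 2
            ) <= dom.radius_um**2
            img[yy[inside], xx[inside]] = dom.membrane_level
    if apply_psf and scene.psf_sigma_xy_px > 0:
        img = ndimage.gaussian_filter(img, scene.psf_sigma_xy_px)
    if not noiseless and scene.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(scene.rng_seed)
        img = img + rng.normal(0.0, scene.noise_sigma, shape)
    return img


def render_zstack(
    scene: VirtualScene, noiseless: bool = False
) -> tuple[ImageStack, pd.DataFrame]:
    """Render the whole stack plus its ground-truth annotation table.

    Sections run from one z-spacing below the lowest vesicle extent to one
    above the highest.  The annotation table lists, per vesicle and per
    section it crosses, the true center (px), true ring radius (px) and the
    true phase label.
    """
    ps = scene.pixel_size_um
    if scene.vesicles:
        z_lo = min(v.center_um[2] - v.radius_um for v in scene.vesicles)
        z_hi = max(v.center_um[2] + v.radius_um for v in scene.vesicles)
        z_lo -= scene.z_spacing_um
        z_hi += scene.z_spacing_um
    else:
        z_lo, z_hi = 0.0, 0.0
    n_z = int(round((z_hi - z_lo) / scene.z_spacing_um)) + 1
    zs = z_lo + scene.z_spacing_um * np.arange(n_z)
    rng = np.random.default_rng(scene.rng_seed)
    sections = np.stack(
        [render_section(scene, z, noiseless=noiseless, rng=rng) for z in zs]
    )
    rows = []
    for i, v in enumerate(scene.vesicles):
        for zi, z in enumerate(zs):
            rho = section_ring_radius_um(v, z)
            if rho is None:
                continue
            rows.append(
                {
                    "vesicle_id": i,
                    "z_index": zi,
                    "z_um": float(z),
                    "cx_px": v.center_um[0] / ps,
                    "cy_px": v.center_um[1] / ps,
                    "r_px": rho / ps,
                    "phase_label": section_phase_label(scene, i, z),
                }
            )
    annotations = pd.DataFrame(
        rows,
        columns=["vesicle_id", "z_index", "z_um", "cx_px", "cy_px", "r_px", "phase_label"],
    )
    stack = ImageStack(
        sections,
        pixel_size=ps,
        z_spacing=scene.z_spacing_um,
        channel_name="virtual",
    )
    return stack, annotations


# ---------------------------------------------------------------------------
# labeled training patches


@dataclass
class LabeledPatchSet:
    """50x50 training patches with integer labels into ``class_names``."""

    patches: np.ndarray  # (n, 50, 50) float32
    labels: np.ndarray  # (n,) int
    class_names: list[str]

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.patches) != len(self.labels):
            raise ValueError("patches and labels must have equal length")
        if self.patches.ndim != 3 or self.patches.shape[1:] != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"patches must be {PATCH_SIZE}x{PATCH_SIZE}")
        if len(self.labels) and not (
            (self.labels >= 0) & (self.labels < len(self.class_names))
        ).all():
            raise ValueError("labels must index class_names")

    def __len__(self) -> int:
        return len(self.patches)


@dataclass
class PatchParams:
    """Sampling ranges for single-vesicle training patches (px units)."""

    ring_radius_px: tuple[float, float] = (14.0, 22.0)
    center_jitter_px: float = 2.0
    membrane_level: tuple[float, float] = (400.0, 800.0)
    background_level: tuple[float, float] = (20.0, 50.0)
    noise_sigma_frac: float = 0.05
    psf_sigma_xy_px: tuple[float, float] = (1.0, 2.0)
    #: domain arc half-angle at the rendered section, degrees
    domain_half_angle_deg: tuple[float, float] = (30.0, 150.0)
    domain_level_frac: tuple[float, float] = (0.15, 0.45)

    def validate(self) -> None:
        for name in (
            "ring_radius_px",
            "membrane_level",
            "background_level",
            "psf_sigma_xy_px",
            "domain_half_angle_deg",
            "domain_level_frac",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")


def _patch_scene(
    params: PatchParams,
    rng: np.random.Generator,
    with_domain: bool,
) -> tuple[VirtualScene, float]:
    """One-vesicle scene whose equatorial section fills a 50x50 frame.

    Uses a pixel size of 1 µm/px so px and µm coincide; the returned z is
    the section height to render (the equator).  When ``with_domain``, a
    domain sphere is centered on the equator so that the in-plane
    intersection arc has exactly the sampled half-angle.
    """
    r_px = _uniform(rng, params.ring_radius_px)
    jit = params.center_jitter_px
    cx = PATCH_SIZE / 2 + rng.uniform(-jit, jit)
    cy = PATCH_SIZE / 2 + rng.uniform(-jit, jit)
    membrane = _uniform(rng, params.membrane_level)
    vesicle = Vesicle(
        center_um=(cx, cy, r_px), radius_um=r_px, membrane_level=membrane
    )
    domains = []
    if with_domain:
        psi = math.radians(_uniform(rng, params.domain_half_angle_deg))
        alpha = rng.uniform(0.0, 2 * math.pi)
        # sphere centered on the ring: in-plane circle-circle intersection
        # at arc half-angle psi requires radius 2*rho*sin(psi/2)
        center = (cx + r_px * math.cos(alpha), cy + r_px * math.sin(alpha), r_px)
        domains.append(
            DomainSphere(
                parent_index=0,
                center_um=center,
                radius_um=2.0 * r_px * math.sin(psi / 2.0),
                membrane_level=_uniform(rng, params.domain_level_frac) * membrane,
            )
        )
    scene = VirtualScene(
        vesicles=[vesicle],
        domains=domains,
        field_of_view_um=float(PATCH_SIZE),
        frame_px=PATCH_SIZE,
        psf_sigma_xy_px=_uniform(rng, params.psf_sigma_xy_px),
        background_level=_uniform(rng, params.background_level),
        noise_sigma=params.noise_sigma_frac * membrane,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )
    return scene, r_px  # equator height equals the vesicle radius here


def zero_background(patch: np.ndarray) -> np.ndarray:
    """Zero all pixels at or below the patch's triangle threshold.

    Sub-threshold pixels are set to zero (not binarized); eliminating the
    background intensity markedly helps the 2-class state CNN.
    """
    out = np.asarray(patch, dtype=float).copy()
    try:
        thr = triangular_threshold(out)
    except ValueError:
        return np.zeros_like(out)
    out[out <= thr] = 0.0
    return out


def _render_patch(scene: VirtualScene, z_um: float, rng: np.random.Generator) -> np.ndarray:
    return render_section(scene, z_um, rng=rng)


def generate_training_set(
    kind: str,
    n_per_class: int,
    params: PatchParams | None = None,
    rng: np.random.Generator | None = None,
) -> LabeledPatchSet:
    """Render a labeled patch set for one of the two CNN tasks.

    ``selection-4class``
        C1 plain unilamellar ring; C2 ring with interior structure
        (multilamellar-like inner shells); C3 two overlapping rings;
        C4 hazy/defocused low-SNR ring.  Raw intensities.
    ``state-2class``
        C1 homogeneous ring vs C2 ring with a domain arc; patches are
        background-thresholded (sub-threshold pixels zeroed).
    """
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    params = params or PatchParams()
    params.validate()
    rng = rng if rng is not None else np.random.default_rng(0)

    patches: list[np.ndarray] = []
    labels: list[int] = []
    if kind == "state-2class":
        class_names = list(STATE_CLASSES)
        for label, with_domain in ((0, False), (1, True)):
            for _ in range(n_per_class):
                scene, z = _patch_scene(params, rng, with_domain)
                patches.append(zero_background(_render_patch(scene, z, rng)))
                labels.append(label)
    elif kind == "selection-4class":
        class_names = list(SELECTION_CLASSES)
        for label in range(4):
            for _ in range(n_per_class):
                scene, z = _patch_scene(params, rng, with_domain=False)
                v = scene.vesicles[0]
                if label == 1:  # multilamellar: inner shell(s) + bright interior
                    inner_r = v.radius_um * rng.uniform(0.4, 0.75)
                    scene.vesicles.append(
                        Vesicle(
                            center_um=v.center_um,
                            radius_um=inner_r,
                            membrane_level=v.membrane_level * rng.uniform(0.6, 1.0),
                            interior_level=v.membrane_level * rng.uniform(0.2, 0.5),
                        )
                    )
                elif label == 2:  # overlapping neighbor
                    ang = rng.uniform(0.0, 2 * math.pi)
                    off = v.radius_um * rng.uniform(0.8, 1.5)
                    r2 = v.radius_um * rng.uniform(0.6, 1.0)
                    scene.vesicles.append(
                        Vesicle(
                            center_um=(
                                v.center_um[0] + off * math.cos(ang),
                                v.center_um[1] + off * math.sin(ang),
                                v.center_um[2],
                            ),
                            radius_um=r2,
                            membrane_level=v.membrane_level * rng.uniform(0.7, 1.0),
                        )
                    )
                elif label == 3:  # hazy: defocused, low contrast, noisy
                    scene.psf_sigma_xy_px = rng.uniform(4.0, 7.0)
                    v.membrane_level *= rng.uniform(0.25, 0.5)
                    scene.noise_sigma *= rng.uniform(1.5, 3.0)
                patches.append(_render_patch(scene, z, rng))
                labels.append(label)
    else:
        raise ValueError(f"unknown training-set kind: {kind!r}")

    patches_arr = np.asarray(patches, dtype=np.float32)
    labels_arr = np.asarray(labels, dtype=int)
    order = rng.permutation(len(labels_arr))
    return LabeledPatchSet(patches_arr[order], labels_arr[order], class_names)


def save_patchset(patch_set: LabeledPatchSet, directory) -> None:
    """Write patches as TIFFs plus a CSV label manifest."""
    import tifffile
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (patch, label) in enumerate(zip(patch_set.patches, patch_set.labels)):
        name = f"patch_{i:06d}.tif"
        tifffile.imwrite(directory / name, patch.astype(np.float32))
        rows.append({"file": name, "label": int(label), "class": patch_set.class_names[label]})
    pd.DataFrame(rows).to_csv(directory / "labels.csv", index=False)
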