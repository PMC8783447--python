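"""Virtual scene sampling, rendering geometry, and training-set contracts."""

import dataclasses

import numpy as np
import pytest

from guvstack.simulate import (
    DomainSphere,
    PatchParams,
    SceneParams,
    Vesicle,
    VirtualScene,
    generate_training_set,
    render_section,
    render_zstack,
    sample_scene,
    section_phase_label,
)


def small_params(**kw):
    defaults = dict(
        n_vesicles=(2, 4),
        radius_um=(8.0, 15.0),
        field_of_view_um=150.0,
        frame_px=150,  # 1 µm/px keeps the tests fast
    )
    defaults.update(kw)
    return SceneParams(**defaults)


class TestSampleScene:
    def test_zero_domain_probability(self, rng):
        scene = sample_scene(
            small_params(n_vesicles=(5, 5), domain_probability=0.0, field_of_view_um=250.0, frame_px=250),
            rng,
        )
        assert len(scene.vesicles) == 5 and len(scene.domains) == 0

    def test_seed_determinism(self):
        params = small_params()
        a = sample_scene(params, np.random.default_rng(123))
        b = sample_scene(params, np.random.default_rng(123))
        assert dataclasses.asdict(a) == dataclasses.asdict(b)

    def test_radii_respect_bounds_over_many_scenes(self, rng):
        params = small_params(n_vesicles=(1, 2), radius_um=(8.0, 15.0))
        radii = []
        for _ in range(1000):
            radii += [v.radius_um for v in sample_scene(params, rng).vesicles]
        assert min(radii) >= 8.0 and max(radii) <= 15.0

    def test_invalid_range_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_scene(small_params(radius_um=(15.0, 8.0)), rng)


def radial_peak_radius(img, cx, cy, background):
    """Independent oracle: argmax of the circularly averaged profile."""
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    d = np.round(np.hypot(xx - cx, yy - cy)).astype(int)
    prof = np.bincount(d.ravel(), weights=(img - background).ravel()) / np.maximum(
        np.bincount(d.ravel()), 1
    )
    return int(np.argmax(prof))


class TestRenderSection:
    def scene_one_vesicle(self, r=10.0, level=600.0, **kw):
        defaults = dict(
            field_of_view_um=64.0,
            frame_px=256,  # 0.25 µm/px
            psf_sigma_xy_px=1.5,
            background_level=40.0,
        )
        defaults.update(kw)
        return VirtualScene(
            vesicles=[Vesicle((32.0, 32.0, 15.0), r, level)], **defaults
        )

    def test_section_beyond_radius_is_background_only(self):
        scene = self.scene_one_vesicle()
        img = render_section(scene, 15.0 + 10.0 + 0.5, noiseless=True)
        assert np.allclose(img, scene.background_level)

    def test_ring_radius_follows_sphere_geometry(self):
        # R = 10 µm, section 6 µm above the equator: ring radius 8 µm
        scene = self.scene_one_vesicle(r=10.0)
        img = render_section(scene, 15.0 + 6.0, noiseless=True)
        peak_px = radial_peak_radius(img, 128.0, 128.0, scene.background_level)
        assert abs(peak_px - 8.0 / scene.pixel_size_um) <= 1

    def test_default_pixel_size(self):
        assert VirtualScene().pixel_size_um == pytest.approx(127.3 / 1024)

    def test_noiseless_unblurred_render_hits_exact_levels(self):
        scene = self.scene_one_vesicle(psf_sigma_xy_px=0.0)
        scene.vesicles[0].interior_level = 120.0
        img = render_section(scene, 15.0, noiseless=True, apply_psf=False)
        assert set(np.unique(img)) == {40.0, 120.0, 600.0}
        peak_px = radial_peak_radius(img, 128.0, 128.0, 40.0)
        assert img[128, 128 + peak_px] == 600.0

    def test_domain_arc_rendered_at_domain_level(self):
        scene = self.scene_one_vesicle(psf_sigma_xy_px=0.0)
        v = scene.vesicles[0]
        scene.domains.append(
            DomainSphere(0, (32.0 + v.radius_um, 32.0, 15.0), 8.0, 150.0)
        )
        img = render_section(scene, 15.0, noiseless=True, apply_psf=False)
        r_px = v.radius_um / scene.pixel_size_um
        assert img[128, 128 + int(r_px)] == 150.0  # inside the arc (+x side)
        assert img[128, 128 - int(r_px)] == 600.0  # opposite side untouched


class TestRenderZstack:
    def test_annotated_section_count(self):
        scene = VirtualScene(
            vesicles=[Vesicle((20.0, 20.0, 8.0), 5.0, 500.0)],
            field_of_view_um=40.0,
            frame_px=80,
        )
        stack, ann = render_zstack(scene, noiseless=True)
        assert len(ann) >= 11  # 2R / z_spacing + 1 sections cross the shell

    def test_annotation_centers_match_render_centroid(self):
        scene = VirtualScene(
            vesicles=[Vesicle((20.0, 22.0, 9.0), 6.0, 800.0)],
            field_of_view_um=40.0,
            frame_px=160,
            psf_sigma_xy_px=1.0,
            background_level=20.0,
        )
        stack, ann = render_zstack(scene, noiseless=True)
        for _, row in ann.iterrows():
            if row.r_px < 5:
                continue
            img = stack[int(row.z_index)]
            mask = img > (20.0 + 800.0) / 4
            ys, xs = np.nonzero(mask)
            assert abs(xs.mean() - row.cx_px) <= 1
            assert abs(ys.mean() - row.cy_px) <= 1

    def test_empty_scene(self):
        stack, ann = render_zstack(VirtualScene(frame_px=32, field_of_view_um=32.0))
        assert np.allclose(stack.sections, VirtualScene().background_level)
        assert len(ann) == 0


class TestPhaseLabels:
    def test_label_matches_dense_arc_sampling(self, rng):
        """Geometric label equals a dense ring-point membership oracle."""
        for _ in range(40):
            r = float(rng.uniform(5, 12))
            scene = VirtualScene(
                vesicles=[Vesicle((25.0, 25.0, 15.0), r, 500.0)],
                field_of_view_um=50.0,
                frame_px=50,
            )
            theta = rng.uniform(0, np.pi)
            phi = rng.uniform(0, 2 * np.pi)
            dom_center = (
                25.0 + r * np.sin(theta) * np.cos(phi),
                25.0 + r * np.sin(theta) * np.sin(phi),
                15.0 + r * np.cos(theta),
            )
            scene.domains.append(
                DomainSphere(0, dom_center, float(rng.uniform(2, 10)), 100.0)
            )
            z = float(rng.uniform(15.0 - r + 0.2, 15.0 + r - 0.2))
            rho = np.sqrt(r**2 - (z - 15.0) ** 2)
            angs = np.linspace(0, 2 * np.pi, 3600, endpoint=False)
            pts = np.stack(
                [25.0 + rho * np.cos(angs), 25.0 + rho * np.sin(angs), np.full_like(angs, z)],
                axis=1,
            )
            d2 = ((pts - np.asarray(dom_center)) ** 2).sum(axis=1)
            expected = "separated" if (d2 < scene.domains[0].radius_um**2).any() else "uniform"
            assert section_phase_label(scene, 0, z) == expected


class TestTrainingSets:
    def test_state_set_counts_and_thresholding(self, rng):
        ps = generate_training_set("state-2class", 100, rng=rng)
        assert len(ps) == 200
        assert np.bincount(ps.labels).tolist() == [100, 100]
        assert ps.class_names == ["C1", "C2"]
        # background zeroing: every patch has zeroed pixels and min exactly 0
        assert all(p.min() == 0.0 for p in ps.patches)
        assert all((p == 0).mean() > 0.2 for p in ps.patches)

    def test_selection_set_counts(self, rng):
        ps = generate_training_set("selection-4class", 25, rng=rng)
        assert len(ps) == 100
        assert np.bincount(ps.labels).tolist() == [25] * 4
        assert ps.class_names == ["C1", "C2", "C3", "C4"]

    def test_determinism(self):
        a = generate_training_set("state-2class", 20, rng=np.random.default_rng(9))
        b = generate_training_set("state-2class", 20, rng=np.random.default_rng(9))
        assert np.array_equal(a.patches, b.patches)
        assert np.array_equal(a.labels, b.labels)

    def test_invalid_count_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_training_set("state-2class", 0, rng=rng)

    def test_homogeneous_contours_less_variable_than_separated(self, rng):
        """Angular coefficient of variation separates the two classes."""
        params = PatchParams(ring_radius_px=(18.0, 18.0), center_jitter_px=0.0)
        ps = generate_training_set("state-2class", 250, params, rng)
        yy, xx = np.mgrid[0:50, 0:50]
        d = np.hypot(xx - 25, yy - 25)
        ang = (np.degrees(np.arctan2(yy - 25, xx - 25)) % 360 / 30).astype(int)
        band = (d > 14) & (d <= 19)
        cvs = {0: [], 1: []}
        for patch, label in zip(ps.patches, ps.labels):
            means = [patch[band & (ang == k)].mean() for k in range(12)]
            cvs[label].append(np.std(means) / np.mean(means))
        assert np.mean(cvs[0]) < np.mean(cvs[1])
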