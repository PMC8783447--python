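"""Patch preparation, augmentation, architecture audit, and training surface."""

import numpy as np
import pytest

from guvstack.classify import (
    PatchClassifier,
    augment,
    build_cnn,
    classify,
    prepare_patch,
)
from guvstack.nn import SmallCnn
from guvstack.segment import CircleDetection
from guvstack.simulate import LabeledPatchSet

from conftest import paint_ring


def circle(cx, cy, r):
    return CircleDetection(z_index=0, cx=cx, cy=cy, r=r)


class TestPreparePatch:
    def test_output_is_always_50x50(self, rng):
        img = rng.uniform(0, 100, (300, 300))
        for r in (5, 40, 90):
            patch = prepare_patch(img, circle(150, 150, r))
            assert patch.shape == (50, 50)

    def test_constant_image_gives_constant_patch(self):
        patch = prepare_patch(np.full((200, 200), 42.0), circle(100, 100, 30))
        assert np.allclose(patch, 42.0)

    def test_matches_independent_bilinear_oracle(self, rng):
        img = rng.uniform(0, 255, (200, 200))
        c = circle(100.0, 100.0, 40.0)
        patch = prepare_patch(img, c, margin=1.2)
        # crop side 2*1.2*40 = 96 px, then endpoint-aligned bilinear to 50x50
        crop = img[52:149, 52:149]  # rounded crop bounds around (100, 100)
        oracle = np.empty((50, 50))
        for i in range(50):
            for j in range(50):
                yf = i * (crop.shape[0] - 1) / 49.0
                xf = j * (crop.shape[1] - 1) / 49.0
                y0, x0 = int(yf), int(xf)
                y1, x1 = min(y0 + 1, crop.shape[0] - 1), min(x0 + 1, crop.shape[1] - 1)
                dy, dx = yf - y0, xf - x0
                oracle[i, j] = (
                    crop[y0, x0] * (1 - dy) * (1 - dx)
                    + crop[y0, x1] * (1 - dy) * dx
                    + crop[y1, x0] * dy * (1 - dx)
                    + crop[y1, x1] * dy * dx
                )
        assert np.abs(patch - oracle).max() <= 1.0

    def test_degenerate_circle_rejected(self):
        with pytest.raises(ValueError):
            prepare_patch(np.zeros((50, 50)), circle(25, 25, 0.5))

    def test_zero_background_thresholding_applied(self):
        img = paint_ring((200, 200), 100, 100, 30, level=900, background=0.0)
        img += 20.0  # flat background offset
        patch = prepare_patch(img, circle(100, 100, 30), zero_bg=True)
        assert patch.min() == 0.0


class TestAugment:
    def patch_set(self, rng, n=10):
        return LabeledPatchSet(
            rng.uniform(0, 100, (n, 50, 50)).astype(np.float32),
            rng.integers(0, 2, n),
            ["C1", "C2"],
        )

    def test_identity_parameters_reproduce_inputs(self, rng):
        ps = self.patch_set(rng)
        out = augment(ps, scale_range=(1.0, 1.0), shift_range=(0.0, 0.0), multiplier=1)
        assert np.array_equal(out.patches, ps.patches)
        assert np.array_equal(out.labels, ps.labels)

    def test_multiplier_replicates_labels(self, rng):
        ps = self.patch_set(rng, n=100)
        out = augment(ps, multiplier=3, rng=rng)
        assert len(out) == 300
        assert np.array_equal(out.labels, np.tile(ps.labels, 3))

    def test_ranges_must_contain_identity(self, rng):
        ps = self.patch_set(rng)
        with pytest.raises(ValueError):
            augment(ps, scale_range=(1.1, 1.3))
        with pytest.raises(ValueError):
            augment(ps, shift_range=(1.0, 3.0))

    def test_shift_is_invertible_on_overlap(self, rng):
        class FixedShiftRng:
            """Always draws the extreme +4 px shift from the offered range."""

            def uniform(self, lo, hi):
                return 4.0

        ps = self.patch_set(rng, n=1)
        shifted = augment(
            ps,
            scale_range=(1.0, 1.0),
            shift_range=(-4.0, 4.0),
            multiplier=1,
            rng=FixedShiftRng(),
        )
        # shifting the content by +4 px means out[i, j] = in[i - 4, j - 4],
        # so the inverse offset recovers the original on the overlap
        orig = ps.patches[0]
        out = shifted.patches[0]
        assert np.allclose(out[10:45, 10:45], orig[6:41, 6:41], atol=1e-4)


class TestArchitectureAudit:
    def test_selection_spec(self):
        spec = build_cnn("selection")
        assert spec.conv_filters == (16, 32, 64)
        assert spec.fc_output == 4

    def test_state_spec(self):
        spec = build_cnn("state")
        assert spec.conv_filters == (8, 16, 32)
        assert spec.fc_output == 2

    @pytest.mark.parametrize("kind", ["selection", "state"])
    def test_layer_sequence(self, kind):
        spec = build_cnn(kind)
        net = SmallCnn(spec.conv_filters, spec.fc_output)
        rows = net.layer_summary()
        types = [r["type"] for r in rows]
        assert types == [
            "input",
            "conv", "batchnorm", "relu", "maxpool",
            "conv", "batchnorm", "relu", "maxpool",
            "conv", "batchnorm", "relu",
            "flatten", "fc", "softmax",
        ]
        convs = [r for r in rows if r["type"] == "conv"]
        assert [c["filters"] for c in convs] == list(spec.conv_filters)
        assert all(c["kernel"] == (3, 3) and c["padding"] == "same" for c in convs)
        pools = [r for r in rows if r["type"] == "maxpool"]
        assert len(pools) == 2
        assert all(p["pool"] == (2, 2) and p["stride"] == (2, 2) for p in pools)
        assert rows[0]["shape"] == (50, 50, 1)
        assert rows[0]["normalization"] == "zerocenter"
        assert [r for r in rows if r["type"] == "fc"][0]["out"] == spec.fc_output

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            build_cnn("other")


def toy_patches(rng, n_per_class=60):
    dark = rng.normal(10, 2, (n_per_class, 50, 50))
    bright = rng.normal(200, 2, (n_per_class, 50, 50))
    x = np.concatenate([dark, bright]).astype(np.float32)
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return x, y


class TestPatchClassifier:
    def test_separable_toy_problem_reaches_full_accuracy(self, rng):
        x, y = toy_patches(rng)
        clf = PatchClassifier(kind="state", random_state=0).fit(x, y)
        assert clf.val_accuracy_ == 1.0
        cls, probs = classify(clf, x[0])
        assert cls == "C1"
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_single_class_rejected(self, rng):
        x, _ = toy_patches(rng, 20)
        with pytest.raises(ValueError):
            PatchClassifier(kind="state").fit(x[:20], np.zeros(20, dtype=int))

    def test_batch_equals_per_patch_classification(self, rng):
        x, y = toy_patches(rng, 30)
        clf = PatchClassifier(kind="state", random_state=0).fit(x, y)
        batch = clf.predict_proba(x[:10])
        singles = np.stack([clf.predict_proba(x[i]) for i in range(10)])
        assert np.allclose(batch, singles, atol=1e-6)

    def test_training_determinism(self, rng):
        x, y = toy_patches(rng, 40)
        a = PatchClassifier(kind="state", random_state=3).fit(x, y)
        b = PatchClassifier(kind="state", random_state=3).fit(x, y)
        assert a.val_accuracy_ == b.val_accuracy_
        assert np.array_equal(a.network_.layers[0].weight, b.network_.layers[0].weight)

    def test_zerocenter_uses_training_statistics(self, rng):
        x, y = toy_patches(rng, 30)
        clf = PatchClassifier(kind="state", random_state=0).fit(x, y)
        assert clf.mean_image_.shape == (50, 50)
        # inference on a constant patch must subtract the training mean,
        # not the patch's own mean
        assert not np.allclose(clf.mean_image_, 0.0)

    def test_save_load_round_trip(self, rng, tmp_path):
        x, y = toy_patches(rng, 30)
        clf = PatchClassifier(kind="state", random_state=0).fit(x, y)
        clf.save(tmp_path / "model")
        loaded = PatchClassifier.load(tmp_path / "model")
        assert np.allclose(clf.predict_proba(x[:8]), loaded.predict_proba(x[:8]))

    def test_sklearn_param_interface(self):
        clf = PatchClassifier(kind="selection", learning_rate=0.02)
        params = clf.get_params()
        assert params["kind"] == "selection"
        clf.set_params(max_epochs=2)
        assert clf.max_epochs == 2
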