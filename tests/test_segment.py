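"""Thresholding and circle detection against brute-force oracles."""

import numpy as np
import pytest
from skimage.filters import threshold_triangle as skimage_triangle

from guvstack.segment import (
    detect_circles,
    make_binary_mask,
    triangular_threshold,
)

from conftest import paint_ring


def brute_force_triangle(image: np.ndarray, nbins: int = 256) -> float:
    """Independent geometric oracle: argmax of point-to-line distance."""
    counts, edges = np.histogram(image, bins=nbins, range=(image.min(), image.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(counts))
    nonzero = np.flatnonzero(counts)
    tail = int(nonzero[np.argmax(np.abs(nonzero - peak))])
    x1, y1, x2, y2 = peak, counts[peak], tail, counts[tail]
    best, best_d = peak, -1.0
    lo, hi = sorted((peak, tail))
    for i in range(lo, hi + 1):
        # distance from (i, counts[i]) to the peak-tail line
        d = abs((y2 - y1) * i - (x2 - x1) * counts[i] + x2 * y1 - y2 * x1) / np.hypot(
            y2 - y1, x2 - x1
        )
        if d > best_d:
            best, best_d = i, d
    return float(centers[best])


class TestTriangularThreshold:
    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            triangular_threshold(np.full((32, 32), 7.0))

    def test_matches_geometric_oracle_on_decaying_histogram(self):
        # tall peak at bin 10 decaying linearly to bin 200
        values = []
        for b in range(10, 201):
            values += [b + 0.5] * (1000 - 5 * (b - 10))
        img = np.array(values, dtype=float).reshape(-1, 1)
        img = np.vstack([img, [[0.5]], [[255.5]]])  # pin the 256-bin range
        assert triangular_threshold(img) == pytest.approx(
            brute_force_triangle(img), abs=1.0
        )

    def test_matches_oracle_on_random_bimodal_images(self, rng):
        for _ in range(10):
            img = np.concatenate(
                [
                    rng.normal(40, 6, 4000),
                    rng.normal(rng.uniform(150, 220), 15, rng.integers(100, 900)),
                ]
            )
            assert triangular_threshold(img.reshape(1, -1)) == pytest.approx(
                brute_force_triangle(img), abs=(img.max() - img.min()) / 256
            )

    def test_separates_two_level_ring(self):
        img = paint_ring((128, 128), 64, 64, 30, level=1000, background=0)
        thr = triangular_threshold(img)
        assert 0 < thr < 1000
        assert make_binary_mask(img, thr)[64, 94]  # a ring pixel survives

    def test_close_to_skimage_variant_on_bimodal_image(self, rng):
        """Cross-check against the established triangle implementation."""
        img = np.concatenate(
            [rng.normal(50, 8, 9000), rng.normal(200, 10, 1000)]
        ).reshape(100, 100)
        ours = triangular_threshold(img)
        theirs = skimage_triangle(img, nbins=256)
        binw = (img.max() - img.min()) / 256
        assert abs(ours - theirs) <= 5 * binw


class TestBinaryMask:
    def test_threshold_extremes(self):
        img = np.arange(12.0).reshape(3, 4)
        assert make_binary_mask(img, -1.0).all()
        assert not make_binary_mask(img, 12.0).any()

    def test_count_matches_pixel_enumeration(self, rng):
        img = rng.choice([10.0, 200.0], size=(40, 40))
        mask = make_binary_mask(img, 100.0)
        assert mask.sum() == int((img == 200.0).sum())


def brute_force_hough(edges, radii, window):
    """Independent accumulator: count edge pixels at distance ~r per center.

    ``window`` restricts candidate centers to (y0, y1, x0, x1).
    """
    ys, xs = np.nonzero(edges)
    y0, y1, x0, x1 = window
    best = (-1, None)
    for r in radii:
        for cy in range(y0, y1):
            d = np.hypot(xs[None, :] - np.arange(x0, x1)[:, None], ys[None, :] - cy)
            votes = (np.abs(d - r) <= 0.5).sum(axis=1)
            i = int(votes.argmax())
            if votes[i] > best[0]:
                best = (int(votes[i]), (x0 + i, cy, r))
    return best[1]


class TestDetectCircles:
    def test_blank_image_yields_nothing(self):
        assert detect_circles(np.zeros((64, 64)), (20, 40)) == []

    def test_invalid_radius_range_rejected(self):
        with pytest.raises(ValueError):
            detect_circles(np.zeros((64, 64)), (40, 20))

    def test_single_ring_recovered_once(self):
        img = paint_ring((256, 256), 100, 100, 30)
        found = detect_circles(img, (20, 120))
        assert len(found) == 1
        det = found[0]
        assert abs(det.cx - 100) <= 2 and abs(det.cy - 100) <= 2
        assert abs(det.r - 30) <= 2

    def test_radius_bounds_exclude_small_ring(self):
        img = paint_ring((128, 128), 64, 64, 10)
        assert detect_circles(img, (20, 120)) == []

    def test_agrees_with_brute_force_accumulator(self):
        img = paint_ring((120, 120), 57, 63, 25)
        found = detect_circles(img, (20, 40))
        assert len(found) == 1
        det = found[0]
        from guvstack.segment import _edge_map

        oracle = brute_force_hough(
            _edge_map(img, use_mask=True),
            range(20, 41),
            (63 - 6, 63 + 7, 57 - 6, 57 + 7),
        )
        ox, oy, orr = oracle
        assert abs(det.cx - ox) <= 2 and abs(det.cy - oy) <= 2
        assert abs(det.r - orr) <= 2

    def test_sensitivity_monotonicity(self, rng):
        img = paint_ring((200, 200), 70, 80, 28) + paint_ring(
            (200, 200), 150, 140, 24, level=600
        )
        img += rng.normal(0, 20, img.shape)
        low = detect_circles(img, (20, 40), sensitivity=0.4)
        high = detect_circles(img, (20, 40), sensitivity=0.8)
        for det in low:
            assert any(
                abs(det.cx - h.cx) < 1e-9
                and abs(det.cy - h.cy) < 1e-9
                and abs(det.r - h.r) < 1e-9
                for h in high
            )

    def test_translation_equivariance(self):
        img = paint_ring((200, 200), 80, 90, 25)
        shifted = np.roll(np.roll(img, 7, axis=0), 11, axis=1)
        base = detect_circles(img, (20, 40))
        moved = detect_circles(shifted, (20, 40))
        assert len(base) == len(moved) == 1
        assert abs(moved[0].cx - base[0].cx - 11) <= 1
        assert abs(moved[0].cy - base[0].cy - 7) <= 1

    def test_recall_on_simulator_ground_truth(self):
        """Isolated noiseless rendered rings are all found within 2 px."""
        from guvstack.simulate import VirtualScene, Vesicle, render_section

        rng = np.random.default_rng(5)
        for _ in range(8):
            r_px = float(rng.uniform(20, 60))
            side = int(2 * r_px + 40)
            cx = side / 2 + rng.uniform(-5, 5)
            cy = side / 2 + rng.uniform(-5, 5)
            scene = VirtualScene(
                vesicles=[Vesicle((cx, cy, r_px), r_px, 800.0)],
                field_of_view_um=float(side),
                frame_px=side,
                psf_sigma_xy_px=1.5,
                background_level=30.0,
            )
            img = render_section(scene, r_px, noiseless=True)
            found = detect_circles(img, (20, 120))
            assert len(found) == 1
            assert np.hypot(found[0].cx - cx, found[0].cy - cy) <= 2
            assert abs(found[0].r - r_px) <= 2
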