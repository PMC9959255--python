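import math

import numpy as np
import pytest
from scipy import ndimage

from dcx.gridding import (
    DetectedRegion,
    GridLayout,
    MaxTree,
    MserParams,
    detect_markers,
    fit_grid,
    quantify_spots,
)
from dcx.simulate import AffineParams, generate_array_scan


# ---------------------------------------------------------------------------
# brute-force oracle for the max-tree / stability computation
# ---------------------------------------------------------------------------

def brute_component_area(img: np.ndarray, seed_pixel: int, t: float) -> int:
    """Area of the component of {img >= t} containing seed, thresholding
    directly; t clamped into [min level of seed's root set, seed level]."""
    flat = img.ravel()
    if flat[seed_pixel] < t:
        t = flat[seed_pixel]
    t = max(t, img.min())  # below global min the whole support is one region
    labels, _ = ndimage.label(img >= t, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    lab = labels.ravel()[seed_pixel]
    return int((labels == lab).sum())


def brute_stability(img: np.ndarray, node: int, tree: MaxTree, delta: float) -> float:
    l = float(tree.flat[node])
    s = int(tree.seed[node])
    a_lo = brute_component_area(img, s, l - delta)
    a_hi = brute_component_area(img, s, l + delta)
    return (a_lo - a_hi) / float(tree.area[node])


class TestMaxTreeOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_areas_and_stability_match_threshold_sweep(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 12, size=(12, 12)).astype(np.int64)
        tree = MaxTree(img)
        nodes = np.flatnonzero(tree.is_node)
        for node in nodes:
            l = int(tree.flat[node])
            s = int(tree.seed[node])
            assert tree.area[node] == brute_component_area(img, s, l)
            for delta in (1, 2, 3):
                assert tree.stability(int(node), delta) == pytest.approx(
                    brute_stability(img, int(node), tree, delta), abs=1e-12
                )

    def test_component_area_every_integer_level(self):
        rng = np.random.default_rng(99)
        img = rng.integers(0, 20, size=(16, 16)).astype(np.int64)
        tree = MaxTree(img)
        for node in np.flatnonzero(tree.is_node)[::3]:
            s = int(tree.seed[node])
            for t in range(int(img.min()), int(img.max()) + 1):
                assert tree.component_area_at(s, t) == brute_component_area(img, s, t)


class TestDetectMarkers:
    def test_noise_free_corner_markers(self, small_layout):
        inten = np.full((4, 4), 20000.0)
        scan, truth = generate_array_scan(small_layout, inten, noise_sd=0.0)
        params = MserParams.for_scan(scan.image, small_layout)
        regions = detect_markers(scan.image, params)
        markers = sorted(regions, key=lambda r: r.stability)[:4]
        assert len(regions) >= 4
        for m in truth.marker_centers:
            d = min(math.hypot(r.centroid[0] - m[0], r.centroid[1] - m[1]) for r in markers)
            assert d <= 0.5

    def test_uniform_image_yields_nothing(self):
        img = np.full((32, 32), 500, dtype=np.uint16)
        assert detect_markers(img, MserParams(min_area=5, max_area=100)) == []

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            detect_markers(np.empty((0, 0)), MserParams(min_area=5, max_area=50))

    def test_no_region_in_area_range_is_empty_list(self):
        img = np.zeros((20, 20), dtype=np.uint16)
        img[8:12, 8:12] = 1000  # 16 px blob
        out = detect_markers(img, MserParams(min_area=100, max_area=200))
        assert out == []

    def test_noisy_markers_recovered(self, small_layout):
        inten = np.full((4, 4), 20000.0)
        scan, truth = generate_array_scan(
            small_layout, inten, noise_sd=0.05 * 65535, seed=11, baseline=5000.0
        )
        params = MserParams.for_scan(scan.image, small_layout)
        regions = detect_markers(scan.image, params)
        assert len(regions) >= 4
        top4 = sorted(regions, key=lambda r: r.stability)[:4]
        for m in truth.marker_centers:
            d = min(math.hypot(r.centroid[0] - m[0], r.centroid[1] - m[1]) for r in top4)
            assert d <= 2.0

    def test_translation_equivariance(self):
        rng = np.random.default_rng(4)
        img = np.full((40, 40), 100, dtype=np.int64)
        img[10:16, 12:18] += 5000
        img += rng.integers(0, 50, img.shape)
        # delta below the noise spread so the blob plateau stays stable
        params = MserParams(delta=10, min_area=9, max_area=120)
        base = detect_markers(img, params)
        dx, dy = 7, 5
        shifted = np.full_like(img, 100)
        shifted[dy:, dx:] = img[:-dy, :-dx]
        moved = detect_markers(shifted, params)
        b = sorted(base, key=lambda r: r.stability)[0]
        s = sorted(moved, key=lambda r: r.stability)[0]
        assert s.centroid[0] - b.centroid[0] == pytest.approx(dx, abs=1e-9)
        assert s.centroid[1] - b.centroid[1] == pytest.approx(dy, abs=1e-9)


class TestFitGrid:
    def _regions(self, pts):
        return [DetectedRegion((float(x), float(y)), 100, 0.0, 1000.0) for x, y in pts]

    def test_exact_translation_recovery(self, small_layout):
        anchors = small_layout.nominal_marker_positions()
        markers = self._regions(anchors + [3.2, -2.7])
        grid = fit_grid(markers, small_layout)
        np.testing.assert_allclose(grid.affine[:, :2], np.eye(2), atol=1e-9)
        np.testing.assert_allclose(grid.affine[:, 2], [3.2, -2.7], atol=1e-9)
        assert grid.residual_rms < 1e-6

    def test_identity_recovery(self, small_layout):
        anchors = small_layout.nominal_marker_positions()
        grid = fit_grid(self._regions(anchors), small_layout)
        np.testing.assert_allclose(grid.affine, [[1, 0, 0], [0, 1, 0]], atol=1e-9)

    def test_exact_affine_recovery_with_rotation(self, small_layout):
        aff = AffineParams(dx=2.0, dy=1.0, rotation_deg=1.0)
        anchors = small_layout.nominal_marker_positions()
        grid = fit_grid(self._regions(aff.apply(anchors)), small_layout)
        np.testing.assert_allclose(grid.affine, aff.matrix(), atol=1e-6)
        assert grid.residual_rms <= 1e-6

    def test_shuffled_markers_matched_by_assignment(self, small_layout):
        anchors = small_layout.nominal_marker_positions()
        pts = (anchors + [1.5, -0.5])[::-1]  # reversed order
        grid = fit_grid(self._regions(pts), small_layout)
        np.testing.assert_allclose(grid.affine[:, 2], [1.5, -0.5], atol=1e-9)

    def test_noisy_markers_residual(self):
        layout = GridLayout(
            rows=4, cols=4, pitch=20, spot_radius=3,
            marker_anchors=((-1, -1), (-1, 4), (4, -1), (4, 4), (-1, 1.5), (4, 1.5)),
        )
        rng = np.random.default_rng(5)
        anchors = layout.nominal_marker_positions()
        noisy = anchors + rng.normal(0, 0.5, anchors.shape)
        grid = fit_grid(self._regions(noisy), layout)
        assert grid.residual_rms <= 1.0
        # affine parameters within 3 standard errors of identity truth:
        # se(translation) ~ sigma/sqrt(n) = 0.5/sqrt(6)
        assert abs(grid.affine[0, 2]) < 3 * 0.5
        assert abs(grid.affine[1, 2]) < 3 * 0.5
        np.testing.assert_allclose(grid.affine[:, :2], np.eye(2), atol=0.05)

    def test_too_few_markers(self, small_layout):
        anchors = small_layout.nominal_marker_positions()
        with pytest.raises(ValueError, match=">= 3"):
            fit_grid(self._regions(anchors[:2]), small_layout)

    def test_collinear_anchors_rejected(self):
        layout = GridLayout(
            rows=3, cols=3, pitch=20, spot_radius=3,
            marker_anchors=((-1, 0), (-1, 1), (-1, 2)),
        )
        pts = layout.nominal_marker_positions()
        with pytest.raises(ValueError, match="collinear"):
            fit_grid([DetectedRegion((x, y), 10, 0.0, 1.0) for x, y in pts], layout)


class TestQuantifySpots:
    def test_noise_free_signal_correlates_with_truth(self, small_layout):
        rng = np.random.default_rng(2)
        inten = rng.uniform(5000, 40000, (4, 4))
        scan, truth = generate_array_scan(small_layout, inten, noise_sd=0.0)
        regions = detect_markers(scan.image, MserParams.for_scan(scan.image, small_layout))
        grid = fit_grid(regions, small_layout)
        quant = quantify_spots(scan.image, grid, small_layout)
        r = np.corrcoef(quant["signal"], truth.planted_spot_intensities.ravel())[0, 1]
        assert r >= 0.99

    def test_blank_image_zero_signals(self, small_layout):
        anchors = small_layout.nominal_marker_positions()
        regions = [DetectedRegion((x, y), 100, 0.0, 1.0) for x, y in anchors]
        grid = fit_grid(regions, small_layout)
        img = np.full(small_layout.canvas_shape(), 777, dtype=np.uint16)
        quant = quantify_spots(img, grid, small_layout)
        assert (quant["signal"] == 0).all()

    def test_edge_spot_flagged_clipped(self, small_layout):
        anchors = small_layout.nominal_marker_positions()
        shift = [DetectedRegion((x - 31.0, y - 31.0), 100, 0.0, 1.0) for x, y in anchors]
        grid = fit_grid(shift, small_layout)
        img = np.full(small_layout.canvas_shape(), 100, dtype=np.uint16)
        quant = quantify_spots(img, grid, small_layout)
        flags = quant.loc[(quant.row == 0) & (quant.col == 0), "flag"]
        assert (flags == "clipped").all()


class TestRobustness:
    def test_localization_error_monotone_in_noise(self, small_layout):
        # seeds-averaged localization error must not decrease with noise
        inten = np.full((4, 4), 25000.0)
        noise_levels = [0.0, 0.03 * 65535, 0.08 * 65535]
        errors = []
        for noise in noise_levels:
            errs = []
            for seed in range(3):
                scan, truth = generate_array_scan(
                    small_layout, inten, noise_sd=noise, seed=seed, baseline=5000.0
                )
                params = MserParams.for_scan(scan.image, small_layout)
                regions = sorted(
                    detect_markers(scan.image, params), key=lambda r: r.stability
                )[:4]
                for m in truth.marker_centers:
                    errs.append(min(
                        math.hypot(r.centroid[0] - m[0], r.centroid[1] - m[1])
                        for r in regions
                    ))
            errors.append(np.mean(errs))
        assert errors[0] <= errors[1] + 0.05
        assert errors[1] <= errors[2] + 0.05
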