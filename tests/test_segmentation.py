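import numpy as np
import pytest
from scipy import ndimage

from pvswidth.contour import trace_perimeter
from pvswidth.segmentation import (
    FilterConfig,
    RatioImage,
    background_peak_threshold,
    close_vessel_boundary,
    compute_ratio_image,
    filter_objects,
    segment_bright_objects,
    threshold_from_histogram,
)

from conftest import make_object, ring_mask


def direct_gaussian_blur(img, sigma, truncate=4.0):
    """Direct (non-separable, non-FFT) Gaussian convolution with reflect padding."""
    r = int(truncate * sigma + 0.5)
    x = np.arange(-r, r + 1)
    k1 = np.exp(-(x**2) / (2.0 * sigma**2))
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    # half-sample symmetric reflection, matching scipy's "reflect" mode
    pad = np.pad(np.asarray(img, float), r, mode="symmetric")
    h, w = img.shape
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = (pad[i : i + 2 * r + 1, j : j + 2 * r + 1] * kernel).sum()
    return out


class TestRatioImage:
    def test_constant_image_gives_unit_ratio(self):
        img = np.full((64, 64), 37.0)
        ratio = compute_ratio_image(img)
        interior = ratio.values[ratio.border_px : -ratio.border_px, ratio.border_px : -ratio.border_px]
        assert np.all(np.abs(interior - 1.0) < 1e-9)

    def test_impulse_is_locally_bright(self):
        img = np.full((64, 64), 10.0)
        img[32, 32] = 1000.0
        ratio = compute_ratio_image(img)
        assert ratio.values[32, 32] > 1.0
        assert abs(ratio.values[5, 5] - 1.0) < 1e-3

    def test_multiplicative_rescale_invariance(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(1, 100, (32, 32))
        r1 = compute_ratio_image(img).values
        r2 = compute_ratio_image(img * 7.5).values
        np.testing.assert_allclose(r1, r2, rtol=0, atol=1e-12)

    def test_matches_direct_convolution_oracle(self):
        img = np.zeros((11, 11))
        img[4:7, 4:7] = 50.0
        img += 5.0
        ratio = compute_ratio_image(img, epsilon=0.0)
        num = direct_gaussian_blur(img, 1.0)
        den = direct_gaussian_blur(img, 4.0)
        np.testing.assert_allclose(ratio.values, num / den, atol=1e-6)

    def test_all_zero_image_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            compute_ratio_image(np.zeros((16, 16)))

    def test_sigma_order_enforced(self):
        with pytest.raises(ValueError, match="sigma"):
            compute_ratio_image(np.ones((16, 16)), sigma_small=4, sigma_large=1)


class TestThresholdRule:
    def test_forced_example(self):
        # counts right of the peak: [90, 76, 40]; 76 < 0.77*100 is the first hit
        counts = [5, 100, 90, 76, 40]
        edges = np.linspace(0.0, 5.0, 6)
        thr = threshold_from_histogram(counts, edges)
        assert thr == edges[3]

    def test_strictly_below_boundary(self):
        # 77 < 0.77*100 is false: no bin qualifies -> error, not a threshold
        counts = [100, 77, 77, 77]
        edges = np.linspace(0, 4, 5)
        with pytest.raises(ValueError, match="no threshold"):
            threshold_from_histogram(counts, edges)

    def test_single_spike_errors(self):
        with pytest.raises(ValueError, match="no threshold"):
            threshold_from_histogram([500], [0.0, 1.0])

    def test_matches_exhaustive_scan_on_random_histograms(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            counts = rng.integers(0, 1000, size=64).astype(float)
            edges = np.linspace(0, 1, 65)
            peak = int(np.argmax(counts))
            expected = None
            for i in range(len(counts)):  # exhaustive scan over all bins
                if i > peak and counts[i] < 0.77 * counts[peak]:
                    expected = edges[i]
                    break
            if expected is None:
                with pytest.raises(ValueError):
                    threshold_from_histogram(counts, edges)
            else:
                assert threshold_from_histogram(counts, edges) == expected

    def test_two_gaussian_mixture_threshold_between_modes(self):
        rng = np.random.default_rng(7)
        bg = rng.normal(1.0, 0.02, size=9000)
        obj = rng.normal(1.5, 0.05, size=1000)
        values = np.concatenate([bg, obj]).reshape(100, 100)
        ratio = RatioImage(values=values, border_px=0)
        thr = background_peak_threshold(ratio)
        # lands between the background mode and the object mode (the drop
        # rule is deliberately permissive: it hugs the background peak)
        assert 1.0 < thr < 1.45
        # agrees with a brute-force scan over all bins of the same histogram
        counts, edges = np.histogram(values.ravel(), bins=256)
        counts = np.convolve(counts.astype(float), np.ones(3) / 3.0, mode="same")
        peak = int(np.argmax(counts))
        expected = next(
            edges[i] for i in range(len(counts)) if i > peak and counts[i] < 0.77 * counts[peak]
        )
        assert thr == expected

    def test_degenerate_ratio_image_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            background_peak_threshold(RatioImage(values=np.ones((16, 16)), border_px=0))


def flood_fill_count(fg):
    """Brute-force 8-connected component count by BFS."""
    fg = fg.copy()
    count = 0
    h, w = fg.shape
    for i in range(h):
        for j in range(w):
            if not fg[i, j]:
                continue
            count += 1
            stack = [(i, j)]
            fg[i, j] = False
            while stack:
                r, c = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and fg[rr, cc]:
                            fg[rr, cc] = False
                            stack.append((rr, cc))
    return count


class TestSegmentObjects:
    def test_two_blobs_two_labels(self):
        v = np.ones((32, 32))
        v[4:8, 4:8] = 3.0
        v[20:25, 20:25] = 3.0
        labels = segment_bright_objects(RatioImage(values=v), threshold=2.0)
        assert labels.max() == 2

    def test_threshold_above_max_gives_zero_labels(self):
        labels = segment_bright_objects(RatioImage(values=np.ones((16, 16))), threshold=5.0)
        assert labels.max() == 0

    def test_component_count_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(0, 2, (64, 64))
        labels = segment_bright_objects(RatioImage(values=v), threshold=1.5)
        assert labels.max() == flood_fill_count(v >= 1.5)


class TestFilterObjects:
    def _one_object(self, area=10):
        labels = np.zeros((32, 32), dtype=int)
        labels[5 : 5 + area, 5] = 1
        channel = np.zeros((32, 32))
        channel[labels == 1] = 100.0
        return labels, channel

    def test_small_object_auto_excluded(self):
        labels, channel = self._one_object(area=10)
        (obj,) = filter_objects(labels, channel, FilterConfig(min_area_px=20))
        assert not obj.selected and obj.selection_source == "auto"

    def test_manual_include_overrides_auto(self):
        labels, channel = self._one_object(area=10)
        (obj,) = filter_objects(
            labels, channel, FilterConfig(min_area_px=20), manual_overrides={1: True}
        )
        assert obj.selected and obj.selection_source == "manual"

    def test_unknown_override_id_errors(self):
        labels, channel = self._one_object()
        with pytest.raises(KeyError, match="nonexistent"):
            filter_objects(labels, channel, manual_overrides={99: True})

    def test_flat_disk_boundary_contrast_is_step_height(self):
        rows, cols = np.mgrid[0:41, 0:41].astype(float)
        disk = np.hypot(rows - 20, cols - 20) <= 8
        labels = disk.astype(int)
        channel = np.where(disk, 100.0, 0.0)
        (obj,) = filter_objects(labels, channel, FilterConfig(min_area_px=1))
        assert obj.boundary_contrast == pytest.approx(100.0)
        assert obj.mean_intensity == pytest.approx(100.0)
        assert obj.area_px == int(disk.sum())

    def test_boundary_contrast_matches_shift_oracle(self):
        rng = np.random.default_rng(9)
        channel = rng.uniform(0, 50, (24, 24))
        labels = np.zeros((24, 24), dtype=int)
        labels[8:15, 6:18] = 1
        (obj,) = filter_objects(labels, channel, FilterConfig(min_area_px=1))
        # independent oracle: per boundary pixel, mean |I(p)-I(q)| over its
        # background 8-neighbors, averaged over boundary pixels
        mask = labels == 1
        vals = []
        for r, c in zip(*np.nonzero(mask)):
            diffs = [
                abs(channel[r, c] - channel[r + dr, c + dc])
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0) and not mask[r + dr, c + dc]
            ]
            if diffs:
                vals.append(np.mean(diffs))
        assert obj.boundary_contrast == pytest.approx(np.mean(vals))

    def test_area_calibration(self):
        labels, channel = self._one_object(area=10)
        (obj,) = filter_objects(labels, channel, FilterConfig(min_area_px=1), pixel_size=0.5)
        assert obj.area_um2 == pytest.approx(10 * 0.25)


class TestCloseVesselBoundary:
    def test_complete_ring_unchanged(self):
        mask = ring_mask((64, 64), (32, 32), outer_r=12, inner_r=8)
        region = close_vessel_boundary(make_object(mask))
        assert np.array_equal(region.closed_mask, mask)
        # perimeter chain covers exactly the outer boundary of the filled ring
        filled = ndimage.binary_fill_holes(mask)
        eroded = ndimage.binary_erosion(filled, structure=np.ones((3, 3)))
        outer = filled & ~eroded
        assert len(region.perimeter) == int(outer.sum())

    def test_gap_closed_and_lumen_sealed(self):
        mask = ring_mask((64, 64), (32, 32), outer_r=12, inner_r=8)
        mask[20:23, 30:34] = False  # cut a ~3 px gap in the wall
        region = close_vessel_boundary(make_object(mask), closing_radius_px=2)
        # flood fill of the background from the border must not reach the lumen
        bg_labels, _ = ndimage.label(~region.closed_mask)
        assert bg_labels[0, 0] != bg_labels[32, 32]

    def test_unclosable_arcs_error(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10, 10:20] = True
        mask[50, 40:50] = True  # two arcs far beyond the closing reach
        with pytest.raises(ValueError, match="not closable"):
            close_vessel_boundary(make_object(mask), closing_radius_px=2, max_iterations=5)

    def test_excluded_object_refused(self):
        mask = ring_mask((64, 64), (32, 32), 12, 8)
        with pytest.raises(ValueError, match="excluded"):
            close_vessel_boundary(make_object(mask, selected=False))


class TestTracePerimeter:
    def test_solid_square_chain(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[2:5, 2:5] = True
        chain = trace_perimeter(mask)
        assert len(chain) == 8  # 3x3 square: all but the center pixel

    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        chain = trace_perimeter(mask)
        assert chain.tolist() == [[2, 2]]

    def test_border_touching_mask_errors(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[0:3, 2:5] = True
        with pytest.raises(ValueError, match="border"):
            trace_perimeter(mask)

    def test_random_blob_matches_boundary_set_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            noise = rng.uniform(size=(48, 48)) < 0.55
            smooth = ndimage.binary_closing(ndimage.binary_opening(noise, np.ones((3, 3))), np.ones((3, 3)))
            # opening with a 2x2 square guarantees >= 2 px thickness, so no
            # boundary pixel is traversed from two sides
            smooth = ndimage.binary_opening(smooth, np.ones((2, 2)))
            labels, n = ndimage.label(smooth, structure=np.ones((3, 3)))
            if n == 0:
                continue
            sizes = ndimage.sum(smooth, labels, range(1, n + 1))
            blob = ndimage.binary_fill_holes(labels == (1 + int(np.argmax(sizes))))
            if blob[0, :].any() or blob[-1, :].any() or blob[:, 0].any() or blob[:, -1].any():
                continue
            chain = trace_perimeter(blob)
            # oracle: mask pixels with >= 1 background 8-neighbor
            eroded = ndimage.binary_erosion(blob, structure=np.ones((3, 3)))
            oracle = set(map(tuple, np.argwhere(blob & ~eroded)))
            assert set(map(tuple, chain)) == oracle
            # consecutive chain pixels (and the wrap-around pair) are 8-adjacent
            diffs = np.abs(np.diff(np.vstack([chain, chain[:1]]), axis=0))
            assert diffs.max() <= 1

    def test_orientation_is_counter_clockwise(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        chain = trace_perimeter(mask)
        x, y = chain[:, 1].astype(float), chain[:, 0].astype(float)
        area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert area2 > 0
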