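"""Flatmount morphometry: geometry, classification, detection, percentiles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import rgcflow as rf
from rgcflow.events import FlatmountImage


class TestAreaDiameter:
    @pytest.mark.parametrize("area,expected", [
        (15.14, 4.39), (17.30, 4.69), (25.95, 5.75), (36.77, 6.84),
        (62.72, 8.94), (140.57, 13.38), (70.0, 9.44),
    ])
    def test_published_area_diameter_pairs(self, area, expected):
        assert rf.area_to_diameter(area) == pytest.approx(expected, abs=5e-3)

    def test_closed_form(self):
        assert rf.area_to_diameter(np.pi / 4) == pytest.approx(1.0)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            rf.area_to_diameter(-1.0)

    @given(st.floats(min_value=0.0, max_value=1e4))
    def test_exact_inverse_of_circle_area(self, d):
        assert rf.area_to_diameter(rf.diameter_to_area(d)) == pytest.approx(
            d, abs=1e-9)


class TestClassification:
    @pytest.mark.parametrize("d,cls", [
        (8.0, "small"), (9.39, "small"), (9.4, "medium"), (10.0, "medium"),
        (12.6, "medium"), (12.61, "large"), (13.0, "large"),
    ])
    def test_boundaries_closed_on_medium(self, d, cls):
        assert rf.classify_by_diameter(d) == cls

    @given(st.floats(min_value=0.0, max_value=50.0, allow_nan=False))
    def test_exhaustive_and_exclusive(self, d):
        assert rf.classify_by_diameter(d) in ("small", "medium", "large")

    def test_vectorised(self):
        out = rf.classify_by_diameter([5.0, 10.0, 20.0])
        assert list(out) == ["small", "medium", "large"]


class TestDensity:
    def test_forty_cells_per_field(self):
        # one 200x200 um field is 0.04 mm^2
        assert rf.density(40, 0.04) == pytest.approx(1000.0)

    def test_zero_cells(self):
        assert rf.density(0, 0.04) == 0.0

    def test_zero_field_area_rejected(self):
        with pytest.raises(ValueError):
            rf.density(10, 0.0)


class TestSizeHistogram:
    @staticmethod
    def _dets(diams):
        return [rf.SomaDetection((0.0, 0.0), rf.diameter_to_area(d), d)
                for d in diams]

    def test_two_micron_bins(self):
        hist = rf.size_histogram(self._dets([1.0, 3.0, 3.9]), 2.0)
        assert list(hist.counts) == [1, 2]
        assert list(hist.bin_edges_um) == [0.0, 2.0, 4.0]

    def test_empty_input(self):
        hist = rf.size_histogram([], 2.0)
        assert hist.counts.sum() == 0

    def test_counts_conserved_random(self):
        rng = np.random.default_rng(11)
        diams = rng.lognormal(1.8, 0.4, 500)
        hist = rf.size_histogram(self._dets(diams), 2.0)
        assert hist.n == 500


class TestEmpiricalPercentile:
    def test_median_of_five(self):
        assert rf.empirical_percentile([1, 2, 3, 4, 5], 50) == 3.0

    def test_bounded_by_max(self):
        x = np.random.default_rng(0).normal(size=100)
        assert rf.empirical_percentile(x, 99.999) <= x.max()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rf.empirical_percentile([], 50)

    def test_matches_sort_and_interpolate_oracle(self):
        # closest-rank linear interpolation, written out by hand
        rng = np.random.default_rng(42)
        for _ in range(200):
            x = rng.lognormal(2.0, 0.7, rng.integers(2, 60))
            q = float(rng.uniform(1, 99))
            s = np.sort(x)
            h = (len(s) - 1) * q / 100.0
            lo = int(np.floor(h))
            expected = s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])
            assert rf.empirical_percentile(x, q) == pytest.approx(expected,
                                                                  rel=1e-12)

    def test_monotone_in_q(self):
        x = np.random.default_rng(5).lognormal(2, 0.5, 300)
        qs = np.linspace(1, 99, 25)
        vals = [rf.empirical_percentile(x, q) for q in qs]
        assert np.all(np.diff(vals) >= 0)


def _disk_image(centers_px, radius_px, shape=(200, 200), scale=0.5):
    img = np.zeros(shape)
    yy, xx = np.ogrid[:shape[0], :shape[1]]
    for cx, cy in centers_px:
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px ** 2] = 200.0
    return FlatmountImage(img, scale=scale)


def _flood_count(mask):
    """Brute-force 8-connected component pixel counts (detection oracle)."""
    seen = np.zeros_like(mask, dtype=bool)
    sizes = []
    h, w = mask.shape
    for sy in range(h):
        for sx in range(w):
            if mask[sy, sx] and not seen[sy, sx]:
                stack, size = [(sy, sx)], 0
                seen[sy, sx] = True
                while stack:
                    y, x = stack.pop()
                    size += 1
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if (0 <= ny < h and 0 <= nx < w and mask[ny, nx]
                                    and not seen[ny, nx]):
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                sizes.append(size)
    return sorted(sizes)


class TestDetectSomata:
    def test_blank_image(self):
        assert rf.detect_somata(FlatmountImage(np.zeros((50, 50)), 0.5)) == []

    def test_grid_of_disks_counted_and_sized(self):
        scale = 0.5
        centers = [(20 + 40 * i, 20 + 40 * j) for i in range(5) for j in range(5)]
        image = _disk_image(centers, radius_px=6, scale=scale)
        dets = rf.detect_somata(image)
        assert len(dets) == 25
        planted = np.pi * (6 * scale) ** 2
        ring = 2 * np.pi * 6 * scale ** 2  # one-pixel perimeter ring
        for det in dets:
            assert abs(det.area_um2 - planted) <= ring

    def test_merged_disks_single_component_area_matches_pixel_oracle(self):
        image = _disk_image([(50, 50), (58, 50)], radius_px=6)
        dets = rf.detect_somata(image)
        assert len(dets) == 1
        oracle = _flood_count(image.pixels > 0)
        assert det_area_px(dets[0], image.scale) == oracle[0]

    def test_fixed_threshold(self):
        img = np.zeros((40, 40))
        img[10:14, 10:14] = 50.0
        dets = rf.detect_somata(FlatmountImage(img, 1.0), threshold=40)
        assert len(dets) == 1 and dets[0].area_um2 == 16.0
        assert rf.detect_somata(FlatmountImage(img, 1.0), threshold=60) == []

    def test_min_area_filters_noise(self):
        img = np.zeros((40, 40))
        img[5, 5] = 200.0          # single-pixel speck
        img[20:26, 20:26] = 200.0  # real soma
        dets = rf.detect_somata(FlatmountImage(img, 1.0), min_area_um2=5.0)
        assert len(dets) == 1

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            FlatmountImage(np.zeros((10, 10)), scale=0.0)


def det_area_px(det: rf.SomaDetection, scale: float) -> int:
    return int(round(det.area_um2 / scale ** 2))
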