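"""Morphological quantification: projections, filters, masks, particles, CAA."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from bamscape.imaging import (
    ImageStack,
    RegionMask,
    analyze_particles,
    area_fraction,
    caa_fraction,
    count_cells,
    make_mask,
    max_project,
    median_filter,
    morph,
    subtract_background,
)
from bamscape.synthetic_data import SyntheticConfig, gen_image_stack


def _stack(data, names=("vessel", "plaque"), px=1.0):
    return ImageStack(np.asarray(data, float), names, px)


class TestMaxProject:
    def test_toy_column_maxima(self):
        data = np.zeros((1, 2, 3, 3))
        data[0, 0] = [[1, 0, 0], [0, 2, 0], [0, 0, 3]]
        data[0, 1] = [[0, 5, 0], [4, 0, 0], [0, 0, 1]]
        plane = max_project(_stack(data, ("c0",)), "c0")
        np.testing.assert_array_equal(
            plane, [[1, 5, 0], [4, 2, 0], [0, 0, 3]]
        )

    def test_single_slice_identity(self, rng):
        data = rng.random((1, 1, 8, 8))
        np.testing.assert_array_equal(max_project(_stack(data, ("c0",)), 0),
                                      data[0, 0])

    def test_missing_channel_is_error(self, rng):
        st = _stack(rng.random((1, 2, 4, 4)), ("c0",))
        with pytest.raises(KeyError):
            max_project(st, "nope")


class TestSubtractBackground:
    def test_constant_plane_zeroed(self):
        out = subtract_background(np.full((80, 80), 17.0), radius=10)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_small_blob_preserved(self):
        yy, xx = np.mgrid[0:128, 0:128]
        blob = 100 * np.exp(-((yy - 64) ** 2 + (xx - 64) ** 2) / (2 * 5**2))
        out = subtract_background(30.0 + blob, radius=50)
        assert abs(out.max() - blob.max()) / blob.max() < 0.05

    def test_generator_background_mostly_removed(self):
        # the generator's smooth low-frequency background model, noiseless
        yy, xx = np.mgrid[0:256, 0:256]
        plane = 20.0 * (0.5 + 0.25 * np.sin(2 * np.pi * yy / 256 + 1.0)
                        + 0.25 * np.cos(2 * np.pi * xx / 256 + 2.0))
        out = subtract_background(plane, radius=50)
        rng_bg = plane.max() - plane.min()
        assert out.max() < 0.05 * rng_bg

    def test_huge_radius_degenerates_to_min_subtraction(self, rng):
        plane = rng.random((20, 20)) + 3.0
        with pytest.warns(UserWarning, match="global minimum"):
            out = subtract_background(plane, radius=25)
        np.testing.assert_allclose(out, plane - plane.min())


class TestMedianFilter:
    def test_constant_unchanged(self):
        plane = np.full((16, 16), 7.0)
        np.testing.assert_array_equal(median_filter(plane, 2), plane)

    def test_impulse_removed(self):
        plane = np.zeros((21, 21))
        plane[10, 10] = 100.0
        assert median_filter(plane, 2).max() == 0.0

    def test_checkerboard_majority(self):
        cb = (np.indices((4, 4)).sum(axis=0) % 2).astype(float)
        out = median_filter(cb, 1)
        # frozen hand evaluation: majority value in each 3x3 (reflected) patch
        expected = np.array(
            [[0, 0, 1, 1], [0, 1, 0, 1], [1, 0, 1, 0], [1, 1, 0, 0]], float
        )
        np.testing.assert_array_equal(out, expected)


class TestMakeMask:
    def test_threshold_above_max_empty(self, rng):
        plane = rng.random((10, 10))
        with pytest.warns(UserWarning, match="all-background"):
            m = make_mask(plane, 2.0)
        assert m.area_px == 0

    def test_zero_threshold_full(self, rng):
        plane = rng.random((10, 10)) + 1.0
        with pytest.warns(UserWarning, match="all-foreground"):
            m = make_mask(plane, 0.0)
        assert m.area_px == 100

    def test_bimodal_exact_separation(self, rng):
        plane = np.full((20, 20), 10.0)
        bright = np.zeros((20, 20), bool)
        bright[5:10, 5:10] = True
        plane[bright] = 200.0
        m = make_mask(plane, 100.0)
        np.testing.assert_array_equal(m.mask, bright)

    def test_otsu_mode_separates_modes(self, rng):
        plane = np.where(rng.random((30, 30)) < 0.3, 200.0, 10.0)
        plane += rng.normal(0, 1, plane.shape)
        m = make_mask(plane, "otsu")
        np.testing.assert_array_equal(m.mask, plane >= 100)


class TestMorph:
    def test_zero_iterations_identity(self, rng):
        m = RegionMask(rng.random((12, 12)) > 0.5)
        out = morph(m, "erode", 0)
        np.testing.assert_array_equal(out.mask, m.mask)

    def test_thin_line_eroded_away(self):
        m = np.zeros((10, 10), bool)
        m[5, 1:9] = True
        assert morph(RegionMask(m), "erode", 1).area_px == 0

    def test_opening_restores_convex_square(self):
        m = np.zeros((100, 100), bool)
        m[20:30, 40:50] = True
        opened = morph(morph(RegionMask(m), "erode", 2), "dilate", 2)
        np.testing.assert_array_equal(opened.mask, m)

    def test_opening_idempotent(self, rng):
        m = RegionMask(ndimage.binary_dilation(rng.random((60, 60)) > 0.9,
                                               iterations=2))
        once = morph(morph(m, "erode", 2), "dilate", 2)
        twice = morph(morph(once, "erode", 2), "dilate", 2)
        np.testing.assert_array_equal(once.mask, twice.mask)


def _floodfill_count(mask: np.ndarray) -> int:
    """Independent oracle: explicit 8-neighbour flood fill."""
    seen = np.zeros_like(mask, bool)
    count = 0
    for sy, sx in zip(*np.nonzero(mask)):
        if seen[sy, sx]:
            continue
        count += 1
        queue = [(sy, sx)]
        seen[sy, sx] = True
        while queue:
            y, x = queue.pop()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if (0 <= ny < mask.shape[0] and 0 <= nx < mask.shape[1]
                            and mask[ny, nx] and not seen[ny, nx]):
                        seen[ny, nx] = True
                        queue.append((ny, nx))
    return count


class TestAnalyzeParticles:
    def test_empty_mask(self):
        ps = analyze_particles(np.zeros((10, 10), bool))
        assert ps.count == 0

    def test_diagonal_touch_merges_with_8_connectivity(self):
        m = np.zeros((10, 10), bool)
        m[2:4, 2:4] = True
        m[4:6, 4:6] = True  # touches only at the corner
        assert analyze_particles(m, connectivity=8).count == 1
        assert analyze_particles(m, connectivity=4).count == 2

    def test_square_area_and_units(self):
        m = np.zeros((100, 100), bool)
        m[10:20, 10:20] = True
        ps = analyze_particles(m, pixel_size_um=0.5)
        assert ps.count == 1
        assert ps.table.loc[0, "area_px"] == 100
        assert ps.table.loc[0, "area_um2"] == pytest.approx(25.0)

    def test_min_area_discards_small(self):
        m = np.zeros((20, 20), bool)
        m[1, 1] = True
        m[10:14, 10:14] = True
        ps = analyze_particles(m, min_area=2)
        assert ps.count == 1
        assert (ps.labels > 0).sum() == 16

    def test_counts_match_floodfill_oracle(self, rng):
        for _ in range(15):
            m = rng.random((40, 40)) > 0.7
            assert analyze_particles(m).count == _floodfill_count(m)


class TestAreaFraction:
    def test_trivial_fractions(self):
        roi = np.ones((100, 100), bool)
        empty = analyze_particles(np.zeros((100, 100), bool))
        assert area_fraction(empty, roi).percent == 0.0
        full = analyze_particles(roi)
        assert area_fraction(full, roi).percent == 100.0
        m = np.zeros((100, 100), bool)
        m[0:10, 0:10] = True
        assert area_fraction(analyze_particles(m), roi).percent == pytest.approx(1.0)

    def test_empty_roi_is_error(self):
        ps = analyze_particles(np.ones((5, 5), bool))
        with pytest.raises(ValueError, match="ROI"):
            area_fraction(ps, np.zeros((5, 5), bool))

    def test_particles_outside_roi_ignored(self):
        m = np.zeros((20, 20), bool)
        m[0:5, 0:5] = True
        roi = np.zeros((20, 20), bool)
        roi[10:20, 10:20] = True
        assert area_fraction(analyze_particles(m), roi).percent == 0.0


class TestCaaFraction:
    @staticmethod
    def _generated(seed, target, snr=5.0):
        cfg = SyntheticConfig(seed=seed, plaque_on_vessel_target=target, snr=snr)
        stack, gt = gen_image_stack(cfg)
        return ImageStack(stack, ("vessel", "plaque")), gt

    def test_zero_plaque_is_zero_percent(self):
        cfg = SyntheticConfig(seed=20, n_plaques=0, plaque_on_vessel_target=0.0,
                              snr=20.0)
        stack, _ = gen_image_stack(cfg)
        st = ImageStack(stack, ("vessel", "plaque"))
        res = caa_fraction(st, "vessel", "plaque", 100.0, 150.0)
        assert res.percent == pytest.approx(0.0, abs=0.5)

    def test_duplicated_channel_full_coverage(self):
        # thick-vessel geometry, where the macro's premise that mask-boundary
        # discretization is negligible actually holds
        cfg = SyntheticConfig(seed=21, snr=20.0, vessel_width_px=13, n_vessels=3)
        stack, _ = gen_image_stack(cfg)
        stack[1] = stack[0]
        st = ImageStack(stack, ("vessel", "plaque"))
        res = caa_fraction(st, "vessel", "plaque", 100.0, 50.0)
        assert res.percent >= 99.0

    def test_generated_target_recovered(self):
        st, gt = self._generated(22, 0.2)
        res = caa_fraction(st, "vessel", "plaque", 100.0, 150.0)
        assert res.percent == pytest.approx(gt.plaque_on_vessel_pct, abs=3.0)

    def test_empty_vessel_mask_is_error(self):
        data = np.full((2, 2, 64, 64), 10.0)
        st = _stack(data)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(ValueError, match="no vessels"):
                caa_fraction(st, "vessel", "plaque", 1e6, 100.0)

    def test_monotone_in_added_inmask_plaque(self):
        st, gt = self._generated(23, 0.1)
        res0 = caa_fraction(st, "vessel", "plaque", 100.0, 150.0)
        # paint extra plaque signal inside the true vessel mask
        extra = gt.vessel_mask & ~gt.plaque_mask
        ys, xs = np.nonzero(extra)
        st.data[1, :, ys[:200], xs[:200]] = 300.0
        res1 = caa_fraction(st, "vessel", "plaque", 100.0, 150.0)
        assert res1.percent >= res0.percent
        # plaque strictly outside the vessel mask must not change CAA%
        st2, _ = self._generated(23, 0.1)
        outside = ~ndimage.binary_dilation(gt.vessel_mask, iterations=6)
        ys, xs = np.nonzero(outside)
        st2.data[1, :, ys[:200], xs[:200]] = 300.0
        res2 = caa_fraction(st2, "vessel", "plaque", 100.0, 150.0)
        assert res2.percent == pytest.approx(res0.percent, abs=1e-9)

    def test_intensity_scale_invariance(self):
        st, _ = self._generated(24, 0.2)
        res1 = caa_fraction(st, "vessel", "plaque", 100.0, 150.0)
        st.data *= 3.0
        res2 = caa_fraction(st, "vessel", "plaque", 300.0, 450.0)
        assert res2.percent == pytest.approx(res1.percent, abs=0.2)


class TestCountCells:
    def test_empty_image_zero_density(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            count, density = count_cells(np.zeros((64, 64)), threshold=10.0,
                                         bg_radius=20)
        assert count == 0
        assert density == 0.0

    def test_disjoint_blobs_counted(self, rng):
        plane = np.full((300, 300), 10.0)
        centers = [(30 + 60 * i, 30 + 60 * j) for i in range(5) for j in range(5)]
        yy, xx = np.mgrid[0:300, 0:300]
        for cy, cx in centers:
            plane += 200 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 3**2))
        plane += rng.normal(0, 2, plane.shape)
        count, density = count_cells(plane, threshold=80.0, pixel_size_um=2.0)
        assert count == 25
        assert density == pytest.approx(25 / (300 * 300 * 4))

    def test_density_halves_with_doubled_area(self, rng):
        plane = np.full((100, 200), 5.0)
        plane[40:50, 40:50] = 250.0
        plane[40:50, 90:100] = 250.0
        roi_half = np.zeros((100, 200), bool)
        roi_half[:, :110] = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, d_full = count_cells(plane, threshold=100.0, bg_radius=30,
                                    roi=np.ones((100, 200), bool))
            _, d_half = count_cells(plane, threshold=100.0, bg_radius=30,
                                    roi=roi_half)
        assert d_full == pytest.approx(d_half * 110 / 200, rel=1e-9)
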