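"""Preprocessing chain: filtering, registration, projection, binarisation, ROI."""

import numpy as np
import pytest

from gliamotion.preprocess import (BinaryCellMovie, GeometryError,
                                   TimeLapseStack, apply_roi, binarise,
                                   max_project, median_filter_frames,
                                   polygon_mask, preprocess_stack, read_tiff,
                                   register_axial, register_lateral,
                                   subtract_background, write_tiff)


class TestMedianFilter:
    def test_constant_image_unchanged(self):
        img = np.full((12, 12), 5.0)
        np.testing.assert_array_equal(median_filter_frames(img, 3), img)

    def test_hot_pixel_rejected(self):
        img = np.zeros((9, 9))
        img[4, 4] = 100.0
        assert median_filter_frames(img, 3).max() == 0.0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            median_filter_frames(np.zeros((5, 5)), 4)

    def test_matches_nested_loop_oracle(self, rng):
        """100 random 8x8 frames against a per-pixel reflected-pad median."""
        for _ in range(100):
            img = rng.random((8, 8))
            out = median_filter_frames(img, 3)
            pad = np.pad(img, 1, mode="symmetric")
            expect = np.empty_like(img)
            for r in range(8):
                for c in range(8):
                    expect[r, c] = np.median(pad[r:r + 3, c:c + 3])
            np.testing.assert_allclose(out, expect)

    def test_applied_per_slice_of_4d_stack(self, rng):
        stack = rng.random((2, 3, 8, 8))
        out = median_filter_frames(stack, 3)
        np.testing.assert_allclose(out[1, 2],
                                   median_filter_frames(stack[1, 2], 3))


class TestBackgroundSubtraction:
    def test_flat_image_maps_to_zero(self):
        assert subtract_background(np.full((40, 40), 7.5), 30).max() == 0.0

    def test_small_disk_preserved_on_flat_background(self):
        img = np.full((80, 80), 10.0)
        yy, xx = np.mgrid[0:80, 0:80]
        disk = (yy - 40) ** 2 + (xx - 40) ** 2 <= 25
        img[disk] += 100.0
        out = subtract_background(img, 30)
        assert out.max() == pytest.approx(100.0, rel=0.05)
        assert np.abs(out[~disk]).mean() < 1.0

    def test_approximately_idempotent(self):
        img = np.full((60, 60), 10.0)
        yy, xx = np.mgrid[0:60, 0:60]
        img[(yy - 30) ** 2 + (xx - 30) ** 2 <= 16] += 50.0
        once = subtract_background(img, 30)
        twice = subtract_background(once, 30)
        assert np.abs(twice - once).max() < 0.02 * img.max()

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros((5, 5)), 0)


class TestLateralRegistration:
    @staticmethod
    def _scene():
        img = np.zeros((64, 64))
        img[20:30, 25:40] = 1.0
        img[40:44, 10:18] = 0.6
        return img

    def test_identical_frames_zero_shift(self):
        img = self._scene()
        _, shifts, flags = register_lateral(np.stack([img] * 4))
        np.testing.assert_array_equal(shifts, 0)
        assert not flags.any()

    def test_constructed_shift_recovered(self):
        img = self._scene()
        shifted = np.roll(np.roll(img, 3, axis=0), -2, axis=1)
        out, shifts, _ = register_lateral(np.stack([img, shifted]))
        np.testing.assert_array_equal(shifts[1], [-3, 2])
        np.testing.assert_allclose(out[1], img)

    def test_robust_to_additive_noise(self, rng):
        """>= 95% exact integer recovery at noise SD = 10% of signal."""
        img = self._scene()
        hits = 0
        trials = 60
        for _ in range(trials):
            dy, dx = rng.integers(-5, 6, size=2)
            noisy = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
            noisy = noisy + rng.normal(0, 0.1, img.shape)
            _, shifts, _ = register_lateral(
                np.stack([img + rng.normal(0, 0.1, img.shape), noisy]))
            hits += np.array_equal(shifts[1], [-dy, -dx])
        assert hits / trials >= 0.95

    def test_all_zero_frame_flagged(self):
        img = self._scene()
        _, shifts, flags = register_lateral(np.stack([img, np.zeros_like(img)]))
        assert flags[1]
        np.testing.assert_array_equal(shifts[1], [0, 0])


class TestAxialRegistration:
    @staticmethod
    def _stack(n_z=9):
        zz, yy, xx = np.mgrid[0:n_z, 0:32, 0:32].astype(float)
        blob = np.exp(-((zz - 4) ** 2 + (yy - 16) ** 2 / 9 +
                        (xx - 16) ** 2 / 9))
        return blob

    def test_no_drift_zero_shifts(self):
        frame = self._stack()
        _, z_shifts, dropped = register_axial(np.stack([frame] * 3))
        np.testing.assert_array_equal(z_shifts, 0)
        assert not dropped.any()

    def test_constructed_z_drift_recovered(self):
        frame = self._stack()
        drifted = np.roll(frame, 2, axis=0)
        out, z_shifts, _ = register_axial(np.stack([frame, drifted]))
        assert z_shifts[1] == -2
        # interior slices restored
        np.testing.assert_allclose(out[1, 1:7], frame[1:7], atol=1e-9)

    def test_excessive_drift_dropped(self):
        zz, yy, xx = np.mgrid[0:9, 0:32, 0:32].astype(float)
        frame = np.exp(-((zz - 1) ** 2 + (yy - 16) ** 2 / 9 +
                         (xx - 16) ** 2 / 9))
        drifted = np.zeros_like(frame)
        drifted[6:] = frame[:3]   # genuine 6-slice drift, zero-filled
        _, z_shifts, dropped = register_axial(np.stack([frame, drifted]))
        assert dropped[1]

    def test_registration_composition_is_identity_on_clean_stack(self):
        frame = self._stack()
        movie = np.stack([frame] * 3)
        lat, _, _ = register_lateral(movie)
        ax, _, _ = register_axial(lat)
        np.testing.assert_allclose(ax, movie)


class TestMaxProject:
    def test_single_slice_identity(self, rng):
        stack = rng.random((3, 1, 6, 6))
        np.testing.assert_array_equal(max_project(stack), stack[:, 0])

    def test_matches_loop_oracle(self, rng):
        stack = rng.random((2, 4, 5, 5))
        out = max_project(stack)
        for t in range(2):
            for r in range(5):
                for c in range(5):
                    assert out[t, r, c] == stack[t, :, r, c].max()


class TestBinarise:
    def test_zero_threshold_all_true(self, rng):
        movie = rng.random((2, 8, 8)) + 0.1
        mask, _, empty = binarise(movie, method="fixed", threshold=0.0)
        assert mask.all() and not empty

    def test_threshold_above_max_flagged_empty(self, rng):
        movie = rng.random((2, 8, 8))
        with pytest.warns(UserWarning):
            mask, _, empty = binarise(movie, method="fixed", threshold=10.0)
        assert empty and not mask.any()

    def test_fixed_requires_threshold(self, rng):
        with pytest.raises(ValueError):
            binarise(rng.random((2, 4, 4)), method="fixed")

    def test_otsu_separates_bimodal_and_matches_histogram_oracle(self, rng):
        lo = np.full((1, 40, 40), 0.2)
        hi = rng.normal(0.8, 0.02, size=(1, 40, 40))
        sel = rng.random((1, 40, 40)) < 0.3
        movie = np.where(sel, hi, lo)
        mask, thr, _ = binarise(movie, method="otsu")
        # the threshold falls in the inter-mode gap: the mask recovers the
        # true mode membership exactly
        np.testing.assert_array_equal(mask, sel)
        np.testing.assert_array_equal(mask, movie >= thr)
        # independent exhaustive inter-class-variance search over 256 bins
        frame = movie.mean(axis=0)
        hist, edges = np.histogram(frame, bins=256)
        mids = 0.5 * (edges[:-1] + edges[1:])
        best, best_var = None, -1.0
        for i in range(1, 256):
            w0, w1 = hist[:i].sum(), hist[i:].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (hist[:i] * mids[:i]).sum() / w0
            m1 = (hist[i:] * mids[i:]).sum() / w1
            var = w0 * w1 * (m0 - m1) ** 2
            if var > best_var:
                best_var, best = var, edges[i]
        np.testing.assert_array_equal(movie >= thr, movie >= best)

    def test_otsu_masks_invariant_to_intensity_scaling(self, rng):
        movie = np.where(rng.random((3, 24, 24)) < 0.2,
                         rng.normal(0.9, 0.05, (3, 24, 24)),
                         rng.normal(0.1, 0.05, (3, 24, 24)))
        m1, _, _ = binarise(movie, method="otsu")
        for k in (0.37, 4.2):
            mk, _, _ = binarise(movie * k, method="otsu")
            np.testing.assert_array_equal(m1, mk)


class TestROI:
    def test_full_frame_polygon_is_identity(self, rng):
        mask = rng.random((2, 16, 16)) > 0.5
        poly = [[-0.5, -0.5], [15.5, -0.5], [15.5, 15.5], [-0.5, 15.5]]
        cell = apply_roi(mask, poly, 0.5, 60.0)
        np.testing.assert_array_equal(cell.mask, mask)

    def test_blob_outside_polygon_removed(self):
        mask = np.zeros((1, 20, 20), dtype=bool)
        mask[0, 2:5, 2:5] = True      # inside
        mask[0, 14:18, 14:18] = True  # outside
        poly = [[0, 0], [9, 0], [9, 9], [0, 9]]
        cell = apply_roi(mask, poly, 0.5, 60.0)
        assert cell.mask[0, 2:5, 2:5].all()
        assert not cell.mask[0, 14:18, 14:18].any()

    def test_self_intersecting_polygon_rejected(self):
        poly = [[0, 0], [10, 10], [10, 0], [0, 10]]  # bowtie
        with pytest.raises(GeometryError):
            polygon_mask(np.asarray(poly, float), (16, 16))

    def test_matches_even_odd_rule_oracle(self, rng):
        """Pixel-in-polygon agrees with a crossing-number oracle at 1000
        random pixel centres."""
        # vertices chosen so no pixel centre lies exactly on an edge
        poly = np.array([[2.3, 1.1], [14.75, 2.9], [11.2, 8.4],
                         [15.1, 13.8], [4.4, 14.2], [7.9, 7.3]])
        inside = polygon_mask(poly, (16, 16))

        def even_odd(x, y):
            cnt = 0
            n = len(poly)
            for i in range(n):
                x1, y1 = poly[i]
                x2, y2 = poly[(i + 1) % n]
                if (y1 > y) != (y2 > y):
                    xc = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
                    if x < xc:
                        cnt += 1
            return cnt % 2 == 1

        pts = rng.integers(0, 16, size=(1000, 2))
        for c, r in pts:
            assert inside[r, c] == even_odd(c, r), (c, r)


class TestTiffRoundTrip:
    def test_calibration_round_trip(self, tmp_path, rng):
        stack = TimeLapseStack(rng.random((2, 3, 10, 10)).astype(np.float32),
                               pixel_size_um=225.0 / 512, z_step_um=2.0,
                               frame_interval_s=30.0)
        path = tmp_path / "stack.tif"
        write_tiff(stack, path)
        back = read_tiff(path)
        assert back.pixel_size_um == pytest.approx(stack.pixel_size_um,
                                                   rel=1e-6)
        assert back.z_step_um == pytest.approx(2.0)
        assert back.frame_interval_s == pytest.approx(30.0)
        np.testing.assert_allclose(back.data, stack.data)


class TestFullChain:
    def test_recovers_ground_truth_masks(self):
        """Background subtraction + median + registration + MIP + Otsu
        recovers >= 0.9 Jaccard overlap with the generator's true masks."""
        from gliamotion.synthetic import SynthConfig, simulate_surveillance

        cfg = SynthConfig(field_width_um=90.0, frame_px=192, n_z=7,
                          n_frames=6, n_cells=2, seed=11,
                          branch_prob_per_um=0.08)
        stack, gt = simulate_surveillance(cfg)
        cells, info = preprocess_stack(stack, ball_radius_px=30)
        rec = cells[0].mask
        true = gt.combined_masks()
        inter = (rec & true).sum()
        union = (rec | true).sum()
        assert inter / union >= 0.9
        np.testing.assert_array_equal(info["lateral_shifts"], 0)
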