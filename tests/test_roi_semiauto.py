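import numpy as np
import pytest
from scipy import ndimage

from qt1seg.exceptions import StageError, ValidationError
from qt1seg.imaging_io import Image2D, Polygon
from qt1seg.phantom import apply_shift, simulate_spgr, spgr_signal
from qt1seg.roi_semiauto import (
    band_mask,
    filter_sd,
    grow_endometrial_roi,
    optimize_shift,
    semiauto_qt1,
    shift_mask,
    trace_contour_mask,
)

FA_LO, FA_HI, TR = 4.0, 18.0, 5.3


def _circle_poly(cx, cy, r, n=32):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Polygon(np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)]))


def _square_poly(x0, y0, x1, y1):
    return Polygon(np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float))


def _image(arr):
    return Image2D(pixels=np.asarray(arr, dtype=float))


def _flood_oracle(img, seed_rc, tol_abs, ref):
    """Independent BFS flood fill (pure python, 8-connected)."""
    rows, cols = img.shape
    admissible = np.abs(img - ref) <= tol_abs
    seen = np.zeros_like(admissible)
    stack = [seed_rc]
    seen[seed_rc] = True
    while stack:
        r, c = stack.pop()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and admissible[rr, cc] and not seen[rr, cc]:
                    seen[rr, cc] = True
                    stack.append((rr, cc))
    return seen


class TestTraceContour:
    def test_square_outline_excludes_interior(self):
        mask = trace_contour_mask(_square_poly(2, 2, 11, 11), (14, 14))
        assert mask[2, 2] and mask[2, 7] and mask[11, 11]
        assert not mask[6, 6]
        # oracle: outline pixels are exactly those on the square's border
        expected = np.zeros((14, 14), dtype=bool)
        expected[2:12, 2] = expected[2:12, 11] = True
        expected[2, 2:12] = expected[11, 2:12] = True
        np.testing.assert_array_equal(mask, expected)

    def test_closed_loop_every_pixel_two_neighbors(self):
        mask = trace_contour_mask(_circle_poly(32, 32, 20), (64, 64))
        padded = np.pad(mask, 1)
        for r, c in zip(*np.nonzero(mask)):
            neigh = padded[r : r + 3, c : c + 3].sum() - 1
            assert neigh >= 2, (r, c)

    def test_contour_separates_interior(self):
        mask = trace_contour_mask(_circle_poly(32, 32, 20), (64, 64))
        fill = ndimage.binary_fill_holes(mask)
        assert fill[32, 32] and fill.sum() > mask.sum()
        # contour AND interior-fill = the boundary layer only
        np.testing.assert_array_equal(fill & mask, mask)

    def test_few_vertices_rejected(self):
        with pytest.raises(ValidationError):
            trace_contour_mask(Polygon(np.array([[0, 0], [5, 5]])), (8, 8))


class TestGrowEndometrium:
    def _disc_scene(self):
        """Disc of intensity 200 (radius 6) inside interior at 100, ring contour."""
        img = np.full((40, 40), 100.0)
        yy, xx = np.mgrid[0:40, 0:40]
        disc = (xx - 20) ** 2 + (yy - 20) ** 2 <= 6**2
        img[disc] = 200.0
        contour = trace_contour_mask(_circle_poly(20, 20, 15), (40, 40))
        img[~ndimage.binary_fill_holes(contour)] = 20.0
        return _image(img), disc, contour

    def test_uniform_disc_grown_fully(self):
        ir, disc, contour = self._disc_scene()
        mask, tol = grow_endometrial_roi(ir, (20, 20), contour)
        np.testing.assert_array_equal(mask, disc)
        # ring (100) enters the window at t=50: |100-200| <= t/100*200
        assert tol == 49

    def test_matches_flood_oracle_at_each_tolerance(self):
        ir, _, contour = self._disc_scene()
        rng = np.random.default_rng(8)
        noisy = _image(ir.pixels + rng.normal(0, 5, ir.shape))
        mask, tol = grow_endometrial_roi(noisy, (20, 20), contour)
        ref = noisy.pixels[20, 20]
        oracle = _flood_oracle(noisy.pixels, (20, 20), tol / 100 * ref, ref)
        np.testing.assert_array_equal(mask, oracle)
        # one more step must hit the contour
        next_comp = _flood_oracle(noisy.pixels, (20, 20), (tol + 1) / 100 * ref, ref)
        assert (next_comp & contour).any()

    def test_isolated_seed_single_pixel(self):
        img = np.full((20, 20), 500.0)
        img[10, 10] = 100.0
        contour = trace_contour_mask(_square_poly(2, 2, 17, 17), (20, 20))
        mask, tol = grow_endometrial_roi(_image(img), (10, 10), contour)
        assert mask.sum() == 1 and mask[10, 10]

    def test_seed_on_contour_rejected(self):
        ir, _, contour = self._disc_scene()
        r, c = next(zip(*np.nonzero(contour)))
        with pytest.raises(ValidationError, match="contour"):
            grow_endometrial_roi(ir, (c, r), contour)

    def test_seed_outside_enclosed_region_rejected(self):
        ir, _, contour = self._disc_scene()
        with pytest.raises(ValidationError, match="outside"):
            grow_endometrial_roi(ir, (1, 1), contour)

    def test_bad_contrast_errors_at_initial_tolerance(self):
        # constant image: the t=3 component floods to the contour immediately
        img = np.full((30, 30), 100.0)
        contour = trace_contour_mask(_circle_poly(15, 15, 10), (30, 30))
        with pytest.raises(ValidationError, match="initial"):
            grow_endometrial_roi(_image(img), (15, 15), contour)


class TestBandMask:
    def test_concentric_discs_annulus(self):
        contour = trace_contour_mask(_circle_poly(20, 20, 15), (40, 40))
        yy, xx = np.mgrid[0:40, 0:40]
        endo = (xx - 20) ** 2 + (yy - 20) ** 2 <= 6**2
        band = band_mask(endo, contour, (40, 40))
        # set-algebra oracle
        interior = ndimage.binary_fill_holes(contour) & ~contour
        np.testing.assert_array_equal(band, interior & ~endo)
        assert not (band & endo).any() and not (band & contour).any()

    def test_endo_fills_interior_rejected(self):
        contour = trace_contour_mask(_circle_poly(10, 10, 7), (20, 20))
        interior = ndimage.binary_fill_holes(contour) & ~contour
        with pytest.raises(ValidationError, match="empty"):
            band_mask(interior, contour, (20, 20))

    def test_empty_endo_gives_full_interior(self):
        contour = trace_contour_mask(_circle_poly(10, 10, 7), (20, 20))
        band = band_mask(np.zeros((20, 20), dtype=bool), contour, (20, 20))
        interior = ndimage.binary_fill_holes(contour) & ~contour
        np.testing.assert_array_equal(band, interior)


class TestFilterSd:
    def test_constant_band_fully_retained(self):
        band = np.zeros((10, 10), dtype=bool)
        band[2:8, 2:8] = True
        kept = filter_sd(_image(np.full((10, 10), 42.0)), band)
        np.testing.assert_array_equal(kept, band)

    def test_gaussian_calibration(self):
        rng = np.random.default_rng(9)
        band = np.ones((100, 100), dtype=bool)
        img = _image(rng.normal(500, 25, (100, 100)))
        kept = filter_sd(img, band)
        assert kept.sum() / band.sum() == pytest.approx(0.95, abs=0.01)

    def test_hand_arithmetic_example(self):
        vals = np.array([[100.0, 100, 100, 100, 100, 200]])
        band = np.ones((1, 6), dtype=bool)
        kept = filter_sd(_image(vals), band)
        # mean 116.67, SD 40.82, cut 80.01 -> only the 200 pixel removed
        assert kept.sum() == 5 and not kept[0, 5]

    def test_single_pixel_band_rejected(self):
        band = np.zeros((4, 4), dtype=bool)
        band[1, 1] = True
        with pytest.raises(ValidationError, match="SD"):
            filter_sd(_image(np.ones((4, 4))), band)


class TestOptimizeShift:
    def _phantom_pair(self, truth, default_spec, dx, dy):
        hi = simulate_spgr(truth, FA_HI, TR)
        fill = float(spgr_signal(default_spec.background.t1,
                                 default_spec.background.m0, FA_HI, TR))
        shifted = apply_shift(hi, dx, dy, fill=fill)
        myo = truth.masks["myometrium"]
        return myo, shifted

    def test_recovers_applied_shift(self, truth, default_spec):
        myo, shifted = self._phantom_pair(truth, default_spec, 3, -2)
        dx, dy, surface = optimize_shift(myo, shifted)
        assert (dx, dy) == (3, -2)
        assert surface[dy + 10, dx + 10] == np.nanmin(surface)

    def test_self_registration(self, truth, default_spec):
        myo, img = self._phantom_pair(truth, default_spec, 0, 0)
        dx, dy, _ = optimize_shift(myo, img)
        assert (dx, dy) == (0, 0)

    def test_constant_image_tiebreak(self):
        myo = np.zeros((64, 64), dtype=bool)
        myo[20:40, 20:40] = True
        dx, dy, surface = optimize_shift(myo, _image(np.full((64, 64), 5.0)))
        assert (dx, dy) == (0, 0)
        assert np.nanmax(surface) == 0.0

    def test_border_shifts_excluded(self):
        myo = np.zeros((30, 30), dtype=bool)
        myo[2:10, 2:10] = True  # 2 px from the top-left: shifts < -2 excluded
        rng = np.random.default_rng(10)
        _, _, surface = optimize_shift(myo, _image(rng.normal(0, 1, (30, 30))))
        assert np.isnan(surface[0, 10])  # dy = -10 impossible
        assert np.isfinite(surface[8, 10])  # dy = -2 fine

    def test_empty_roi_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            optimize_shift(np.zeros((10, 10), dtype=bool), _image(np.ones((10, 10))))

    def test_fixed_reference_mode(self, truth, default_spec):
        myo, shifted = self._phantom_pair(truth, default_spec, 2, 1)
        dx, dy, _ = optimize_shift(myo, shifted, ref_mean="fixed")
        assert (dx, dy) == (2, 1)


class TestSemiautoPipeline:
    def test_registered_phantom_recovers_t1(self, truth, default_spec,
                                            noiseless_images, noiseless_t1map,
                                            outer_polygon):
        res = semiauto_qt1(noiseless_images["ir"], noiseless_images["hi"],
                           noiseless_t1map, (64, 64), outer_polygon)
        assert res.mean_qt1 == pytest.approx(default_spec.myometrium.t1, rel=1e-3)
        assert res.optimal_shift == (0, 0)
        assert res.tolerance_pct >= 3

    def test_shifted_phantom_recovers_shift_and_t1(self, truth, default_spec,
                                                   noiseless_images, outer_polygon):
        from qt1seg.t1_mapping import compute_t1_map

        fill_lo = float(spgr_signal(default_spec.background.t1,
                                    default_spec.background.m0, FA_LO, TR))
        fill_hi = float(spgr_signal(default_spec.background.t1,
                                    default_spec.background.m0, FA_HI, TR))
        lo = apply_shift(noiseless_images["lo"], 3, -2, fill=fill_lo)
        hi = apply_shift(noiseless_images["hi"], 3, -2, fill=fill_hi)
        t1map = compute_t1_map(lo, hi)
        res = semiauto_qt1(noiseless_images["ir"], hi, t1map, (64, 64), outer_polygon)
        assert res.optimal_shift == (3, -2)
        assert res.mean_qt1 == pytest.approx(default_spec.myometrium.t1, rel=1e-3)

    def test_deterministic(self, noiseless_images, noiseless_t1map, outer_polygon):
        a = semiauto_qt1(noiseless_images["ir"], noiseless_images["hi"],
                         noiseless_t1map, (64, 64), outer_polygon)
        b = semiauto_qt1(noiseless_images["ir"], noiseless_images["hi"],
                         noiseless_t1map, (64, 64), outer_polygon)
        assert a.mean_qt1 == b.mean_qt1
        assert a.optimal_shift == b.optimal_shift
        assert a.tolerance_pct == b.tolerance_pct
        np.testing.assert_array_equal(a.endo_mask, b.endo_mask)
        np.testing.assert_array_equal(a.myo_mask, b.myo_mask)
        np.testing.assert_array_equal(a.ssd_surface, b.ssd_surface)

    def test_result_invariants(self, noiseless_images, noiseless_t1map, outer_polygon):
        res = semiauto_qt1(noiseless_images["ir"], noiseless_images["hi"],
                           noiseless_t1map, (64, 64), outer_polygon)
        assert not (res.endo_mask & res.myo_mask).any()
        assert (res.myo_mask & ~res.band_mask).sum() == 0  # myo subset of band
        assert res.ssd_surface.shape == (21, 21)
        dx, dy = res.optimal_shift
        assert abs(dx) <= 10 and abs(dy) <= 10

    def test_stage_labels_on_error(self, noiseless_images, noiseless_t1map,
                                   outer_polygon):
        with pytest.raises(StageError, match="grow_endometrium"):
            # seed in the background, outside the enclosed region
            semiauto_qt1(noiseless_images["ir"], noiseless_images["hi"],
                         noiseless_t1map, (2, 2), outer_polygon)

    def test_robustness_vs_manual_under_jitter(self, truth, default_spec):
        """Semiauto mean qT1 disperses less than manual under contour jitter."""
        from qt1seg.roi_manual import manual_myometrial_mask, mean_qt1
        from qt1seg.t1_mapping import compute_t1_map
        from qt1seg.phantom import simulate_ir

        sd = 0.02 * float(spgr_signal(default_spec.myometrium.t1,
                                      default_spec.myometrium.m0, FA_LO, TR))
        lo = simulate_spgr(truth, FA_LO, TR, noise_sd=sd, seed=21)
        hi = simulate_spgr(truth, FA_HI, TR, noise_sd=sd, seed=22)
        ir = simulate_ir(truth, 200.0, noise_sd=sd, seed=23)
        t1map = compute_t1_map(lo, hi)
        outer = default_spec.outer.polygon(24)
        inner = default_spec.inner.polygon(24)
        rng = np.random.default_rng(24)
        manual_vals, semi_vals = [], []
        for _ in range(20):
            whole = Polygon(outer + rng.normal(0, 2, outer.shape))
            endo = Polygon(inner + rng.normal(0, 2, inner.shape))
            manual_vals.append(
                mean_qt1(manual_myometrial_mask(whole, endo, truth.labels.shape), t1map)
            )
            semi_vals.append(
                semiauto_qt1(ir, hi, t1map, (64, 64), whole).mean_qt1
            )
        assert np.std(semi_vals) < np.std(manual_vals)


class TestShiftMask:
    def test_round_trip(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:10, 6:12] = True
        out = shift_mask(shift_mask(mask, 3, -2), -3, 2)
        np.testing.assert_array_equal(out, mask)
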