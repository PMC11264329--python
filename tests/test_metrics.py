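"""ROI extraction, SBR formulas, ramp curves, collapse fitting, dB scaling."""

import numpy as np
import pytest

from gvscreen import (
    CollapseState,
    ROIStats,
    SBRCurve,
    WellGrid,
    fit_collapse_midpoint,
    nonlinear_difference_sbr,
    nonlinear_response,
    pre_post_difference_sbr,
    pre_post_protocol,
    ramp_curves,
    roi_means,
    run_protocol,
    sbr,
    to_decibels,
    voltage_ramp_protocol,
)
from gvscreen.metrics import _logistic_decay


def pixel_loop_roi_means(image, grid):
    """Exhaustive per-pixel oracle for disk-ROI means (Euclidean membership)."""
    h, w = image.shape
    well_sums, well_counts = {}, {}
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            cy, cx = grid.well_center(r, c)
            total = n = 0
            for y in range(h):
                for x in range(w):
                    if (y - cy) ** 2 + (x - cx) ** 2 <= grid.roi_radius**2:
                        total += image[y, x]
                        n += 1
            name = f"{chr(65 + r)}{c + 1}"
            well_sums[name], well_counts[name] = total, n
    bg_total = bg_n = 0
    for cy, cx in grid.background_centers:
        for y in range(h):
            for x in range(w):
                if (y - cy) ** 2 + (x - cx) ** 2 <= grid.background_radius**2:
                    bg_total += image[y, x]
                    bg_n += 1
    return (
        {k: well_sums[k] / well_counts[k] for k in well_sums},
        well_counts,
        bg_total / bg_n,
        bg_n,
    )


def random_small_grid(rng):
    n_rows = int(rng.integers(1, 3))
    n_cols = int(rng.integers(1, 3))
    radius = float(rng.uniform(2.0, 5.0))
    pitch = float(rng.uniform(4 * radius, 5 * radius))
    origin = (float(rng.uniform(radius + 1, radius + 4)),
              float(rng.uniform(radius + 1, radius + 4)))
    bg = (origin[0] + pitch / 2, origin[1] + pitch / 2)
    h = int(np.ceil(max(origin[0] + (n_rows - 1) * pitch, bg[0]) + radius + 2))
    w = int(np.ceil(max(origin[1] + (n_cols - 1) * pitch, bg[1]) + radius + 2))
    return WellGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        origin=origin,
        pitch=(pitch, pitch),
        roi_radius=radius,
        background_centers=(bg,),
        background_radius=radius,
        image_shape=(h, w),
    )


class TestRoiMeans:
    def test_constant_image_all_means_equal(self, small_grid):
        image = np.full(small_grid.image_shape, 3.25)
        stats = roi_means(image, small_grid)
        assert all(v == pytest.approx(3.25) for v in stats.well_means.values())
        assert stats.background_mean == pytest.approx(3.25)

    def test_bright_disk_at_a1(self, small_grid):
        image = np.ones(small_grid.image_shape)
        ys, xs, mask = small_grid.disk_mask(
            small_grid.well_center(0, 0), small_grid.roi_radius
        )
        block = image[ys, xs]
        block[mask] = 9.0
        image[ys, xs] = block
        stats = roi_means(image, small_grid)
        assert all(
            stats.well_means["A1"] > v
            for k, v in stats.well_means.items()
            if k != "A1"
        )

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_pixel_loop(self, trial):
        rng = np.random.default_rng(100 + trial)
        grid = random_small_grid(rng)
        image = rng.uniform(0.1, 10.0, size=grid.image_shape)
        stats = roi_means(image, grid)
        means, counts, bg_mean, bg_n = pixel_loop_roi_means(image, grid)
        assert stats.well_pixel_counts == counts
        assert stats.background_pixel_count == bg_n
        for k in means:
            assert stats.well_means[k] == pytest.approx(means[k], rel=1e-12)
        assert stats.background_mean == pytest.approx(bg_mean, rel=1e-12)

    def test_shape_mismatch_errors(self, small_grid):
        with pytest.raises(ValueError, match="shape"):
            roi_means(np.ones((5, 5)), small_grid)


def _stats(sample, background, voltage=None, well="A1"):
    return ROIStats(
        well_means={well: sample},
        well_pixel_counts={well: 100},
        background_mean=background,
        background_pixel_count=100,
        voltage=voltage,
    )


class TestSBRFormulas:
    def test_difference_sbr_formula(self):
        out = nonlinear_difference_sbr(_stats(12.0, 99.0), _stats(2.0, 2.0))
        assert out["A1"] == pytest.approx(5.0)

    def test_identical_stats_give_zero(self):
        s = _stats(7.3, 2.1)
        assert nonlinear_difference_sbr(s, s)["A1"] == 0.0

    def test_voltage_mismatch_errors(self):
        with pytest.raises(ValueError, match="voltage"):
            nonlinear_difference_sbr(_stats(5, 2, voltage=2.0), _stats(1, 2, voltage=3.0))

    def test_zero_background_errors(self):
        with pytest.raises(ValueError):
            nonlinear_difference_sbr(_stats(5, 2), _stats(1, 0.0))
        with pytest.raises(ValueError):
            sbr(_stats(5, 0.0))

    def test_plain_sbr(self):
        assert sbr(_stats(6.0, 2.0))["A1"] == pytest.approx(3.0)
        assert sbr(_stats(2.0, 2.0))["A1"] == pytest.approx(1.0)

    def test_difference_sbr_scale_invariant(self):
        a = nonlinear_difference_sbr(_stats(12.0, 4.0), _stats(2.0, 2.0))["A1"]
        b = nonlinear_difference_sbr(_stats(12.0 * 7, 4.0 * 7), _stats(2.0 * 7, 2.0 * 7))["A1"]
        assert a == pytest.approx(b)

    def test_noiseless_simulator_matches_closed_form(
        self, small_grid, noiseless, gv_well
    ):
        stack = run_protocol(
            pre_post_protocol(imaging_voltage=4.4),
            small_grid,
            {"A1": gv_well},
            noiseless,
            seed=0,
        )
        observed = pre_post_difference_sbr(stack, small_grid)
        a_eff = nonlinear_response(gv_well, 4.4 * 50.0)
        assert observed["A1"] == pytest.approx(a_eff / 2.0, rel=1e-9)
        for well in ("A2", "B3"):
            assert observed[well] == pytest.approx(0.0, abs=1e-12)


def test_null_plate_difference_sbr_bounded(small_grid):
    """An all-empty plate gives |difference SBR| below a 4/sqrt(n_pixels)
    scale bound (several standard deviations of the speckle-limited null)."""
    from gvscreen import NoiseModel

    noise = NoiseModel(background_mean=2.0, speckle=True)
    n_pixels = None
    for seed in range(8):
        stack = run_protocol(pre_post_protocol(), small_grid, {}, noise, seed=seed)
        diff = pre_post_difference_sbr(stack, small_grid)
        if n_pixels is None:
            stats = roi_means(stack.frames[0], small_grid)
            n_pixels = min(stats.well_pixel_counts.values())
        for value in diff.values():
            assert abs(value) < 4.0 / np.sqrt(n_pixels)


class TestRampCurves:
    def test_voltage_ramp_point_per_voltage(self, small_grid, noiseless, gv_well):
        vs = [2.0, 2.5, 3.0, 3.5, 4.0]
        stack = run_protocol(
            voltage_ramp_protocol(vs), small_grid, {"A1": gv_well}, noiseless, seed=0
        )
        curves = ramp_curves(stack, small_grid)
        assert all(len(c.x) == 5 for c in curves.values())
        assert list(curves["A1"].x) == vs

    def test_missing_post_partner_errors(self, small_grid, noiseless, gv_well):
        stack = run_protocol(
            voltage_ramp_protocol([2.0, 3.0]), small_grid, {"A1": gv_well}, noiseless, seed=0
        )
        stack.meta.loc[stack.meta["phase"] == "postcollapse", "voltage"] += 0.1
        with pytest.raises(ValueError, match="no postcollapse frame"):
            ramp_curves(stack, small_grid)

    def test_empty_well_collapse_ramp_sbr_near_one(self, small_grid, noiseless):
        from gvscreen import collapse_ramp_protocol

        stack = run_protocol(
            collapse_ramp_protocol([3.0, 4.0, 5.0, 6.0]),
            small_grid,
            {},
            noiseless,
            seed=0,
        )
        curves = ramp_curves(stack, small_grid)
        for c in curves.values():
            assert all(v == pytest.approx(1.0) for v in c.y)

    def test_abscissa_must_increase(self):
        with pytest.raises(ValueError):
            SBRCurve((1.0, 1.0, 2.0), (0.0, 0.0, 0.0), "sbr")


class TestCollapseFit:
    def test_exact_logistic_recovered_to_machine_precision(self):
        x = np.linspace(100.0, 500.0, 12)
        y = _logistic_decay(x, 1.0, 8.0, 300.0, 20.0)
        fit = fit_collapse_midpoint(SBRCurve(tuple(x), tuple(y), "sbr"))
        assert fit.success
        assert fit.midpoint == pytest.approx(300.0, abs=1e-6)
        assert fit.plateau == pytest.approx(8.0, rel=1e-6)
        assert fit.baseline == pytest.approx(1.0, rel=1e-6)

    def test_grid_search_oracle_confirms_optimum(self):
        """A coarse brute-force (midpoint, width) search never beats the
        least-squares optimum."""
        rng = np.random.default_rng(0)
        x = np.linspace(100.0, 500.0, 15)
        y = _logistic_decay(x, 1.0, 8.0, 310.0, 25.0) + rng.normal(0, 0.05, x.size)
        curve = SBRCurve(tuple(x), tuple(y), "sbr")
        fit = fit_collapse_midpoint(curve)
        assert fit.success
        sse_fit = np.sum(
            (y - _logistic_decay(x, fit.baseline, fit.plateau, fit.midpoint, fit.width)) ** 2
        )
        for mid in np.linspace(150, 450, 40):
            for width in np.linspace(5, 80, 20):
                sse = np.sum((y - _logistic_decay(x, 1.0, 8.0, mid, width)) ** 2)
                assert sse_fit <= sse + 1e-9
        assert abs(fit.midpoint - 310.0) < 15.0

    def test_flat_curve_flags_failure_without_raising(self):
        curve = SBRCurve(tuple(range(4)), (2.0, 2.0, 2.0, 2.0), "sbr")
        fit = fit_collapse_midpoint(curve)
        assert not fit.success

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            fit_collapse_midpoint(SBRCurve((1.0, 2.0, 3.0), (3.0, 2.0, 1.0), "sbr"))

    def test_normalized_fit_midpoint_unchanged(self):
        x = np.linspace(100.0, 500.0, 12)
        y = _logistic_decay(x, 0.5, 40.0, 320.0, 30.0)
        raw = fit_collapse_midpoint(SBRCurve(tuple(x), tuple(y), "sbr"))
        norm = fit_collapse_midpoint(SBRCurve(tuple(x), tuple(y), "sbr"), normalize=True)
        assert raw.success and norm.success
        assert norm.midpoint == pytest.approx(raw.midpoint, rel=1e-6)


class TestDecibels:
    def test_reference_maps_to_zero(self):
        assert to_decibels(np.array([[2.0]]), 2.0)[0, 0] == 0.0

    def test_10x_reference_is_20db(self):
        assert to_decibels(np.array([[20.0]]), 2.0)[0, 0] == pytest.approx(20.0)

    def test_zero_pixel_clamped_to_floor(self):
        assert to_decibels(np.array([[0.0]]), 2.0)[0, 0] == -60.0

    def test_nonpositive_reference_errors(self):
        with pytest.raises(ValueError):
            to_decibels(np.ones((2, 2)), 0.0)
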