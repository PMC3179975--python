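"""Series post-processing: exclusions, baseline, alignment, scaling,
variance-stabilising transforms, bucketing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nmrproc import postproc as pp
from nmrproc.core import SpectrumSeries

N_POINTS = 2200
PPM = np.linspace(10.0, -1.0, N_POINTS)
X = np.linspace(-1.0, 1.0, N_POINTS)


def gaussian_peak(center, width, height):
    return height * np.exp(-0.5 * ((PPM - center) / width) ** 2)


SIGNAL = (gaussian_peak(3.0, 0.02, 50.0) + gaussian_peak(7.0, 0.03, 20.0)
          + gaussian_peak(0.0, 0.01, 30.0))


def make_series(matrix, **kw):
    return SpectrumSeries(np.atleast_2d(np.asarray(matrix, float)).copy(),
                          PPM.copy(), **kw)


class TestExclusionsAndClasses:
    def test_exclusion_mask_covers_closed_interval(self):
        s = pp.exclude_regions(make_series([SIGNAL, SIGNAL]), [(4.5, 5.2)])
        inside = (PPM >= 4.5) & (PPM <= 5.2)
        np.testing.assert_array_equal(s.included_mask, ~inside)

    def test_overlapping_regions_union(self):
        s = pp.exclude_regions(make_series([SIGNAL]), [(4.5, 5.2), (5.0, 5.5)])
        inside = (PPM >= 4.5) & (PPM <= 5.5)
        np.testing.assert_array_equal(s.included_mask, ~inside)

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            pp.exclude_regions(make_series([SIGNAL]), [(5.2, 4.5)])

    def test_full_axis_exclusion_breaks_scaling(self):
        s = pp.exclude_regions(make_series([SIGNAL, SIGNAL]), [(-2.0, 11.0)])
        with pytest.raises(ValueError, match="included"):
            pp.scale_total_area(s)

    def test_exclude_then_include_restores(self):
        s = make_series([SIGNAL, SIGNAL, SIGNAL])
        out = pp.include_spectra(pp.exclude_spectra(s, [1]), [1])
        np.testing.assert_array_equal(out.included_spectra, [True] * 3)

    def test_duplicate_exclusion_idempotent(self):
        s = pp.exclude_spectra(make_series([SIGNAL, SIGNAL]), [0])
        again = pp.exclude_spectra(s, [0])
        np.testing.assert_array_equal(s.included_spectra, again.included_spectra)

    def test_relabel_round_trip(self):
        s = make_series([SIGNAL, SIGNAL], classes=["a", "b"])
        out = pp.assign_classes(pp.assign_classes(s, ["x", "y"]), ["a", "b"])
        assert out.classes == ["a", "b"]

    def test_unknown_spectrum_id_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            pp.exclude_spectra(make_series([SIGNAL]), [5])


ANCHORS = (9.5, 8.5, 8.0, 6.0, 5.0, 4.0, 2.0, 1.0, -0.5)


class TestBaselineSpline:
    def test_spline_representable_baseline_removed_at_anchors(self):
        from scipy.interpolate import CubicSpline
        idx = np.sort([int(np.argmin(np.abs(PPM - p))) for p in ANCHORS])
        values = np.array([3.0, -1.0, 2.0, 4.0, -2.0, 1.0, 0.5, 2.5, -1.5])
        base = CubicSpline(idx.astype(float), values, bc_type="natural")(
            np.arange(N_POINTS, dtype=float))
        s = make_series([base, base * 0.5])
        out = pp.baseline_spline(s, pp.BaselineSplineParams(ANCHORS, 1))
        scale = np.abs(base).max()
        for row in out.matrix:
            assert np.max(np.abs(row[idx])) < 1e-9 * scale

    def test_zero_baseline_leaves_spectrum_unchanged(self):
        s = make_series([SIGNAL])
        out = pp.baseline_spline(s, pp.BaselineSplineParams(ANCHORS, 3))
        # anchors sit in signal-free zones where the spectrum is ~0
        np.testing.assert_allclose(out.matrix[0], SIGNAL, atol=1e-10)

    def test_polynomial_baseline_reduced_100x_in_peak_free_zones(self):
        base = np.polynomial.polynomial.polyval(X, [0.5, 2.0, -3.0, 1.0])
        s = make_series([SIGNAL + base, 2.0 * SIGNAL + base])
        out = pp.baseline_spline(s, pp.BaselineSplineParams(ANCHORS, 1))
        free = ((np.abs(PPM - 3.0) > 0.3) & (np.abs(PPM - 7.0) > 0.3)
                & (np.abs(PPM) > 0.3))
        rms_before = np.sqrt(np.mean(base[free] ** 2))
        rms_after = np.sqrt(np.mean(out.matrix[0][free] ** 2))
        assert rms_before / rms_after >= 100.0

    def test_too_few_anchors_rejected(self):
        with pytest.raises(ValueError, match="4"):
            pp.BaselineSplineParams((1.0, 2.0, 3.0), 1)

    def test_even_average_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            pp.BaselineSplineParams(ANCHORS, 2)

    def test_linear_mode_bridges_wide_gaps_linearly(self):
        base = np.polynomial.polynomial.polyval(X, [1.0, 0.0, 4.0])
        s = make_series([base])
        wide = (9.5, 9.0, 8.5, -0.5)  # huge central gap
        out = pp.baseline_spline(
            s, pp.BaselineSplineParams(wide, 1, linear=True, linear_points=300))
        lin = pp.baseline_spline(s, pp.BaselineSplineParams(wide, 1))
        # in the bridged segment the two differ (line vs natural spline)
        mid = np.abs(PPM - 4.0) < 1.0
        assert not np.allclose(out.matrix[0][mid], lin.matrix[0][mid])


class TestAlignment:
    def test_planted_integer_shifts_recovered_exactly(self):
        shifts = [-3, 0, 5]
        s = make_series([np.roll(SIGNAL, k) for k in shifts])
        out = pp.align_to_reference(s, 0)
        rec = out.post_state[-1][1]["shifts"]
        assert rec == [shifts[0] - k for k in shifts]
        np.testing.assert_array_equal(out.matrix[1], out.matrix[0])

    def test_reference_against_itself_is_zero_shift(self):
        s = make_series([SIGNAL, SIGNAL.copy()])
        assert pp.align_to_reference(s, 0).post_state[-1][1]["shifts"] == [0, 0]

    def test_chosen_lag_correlation_dominates_lag_zero(self):
        rng = np.random.default_rng(1)
        s = make_series([SIGNAL, np.roll(SIGNAL, 7) + rng.normal(0, 0.1, N_POINTS)])
        out = pp.align_to_reference(s, 0)
        lag = out.post_state[-1][1]["shifts"][1]
        ref, row = s.matrix[0], s.matrix[1]
        assert np.dot(ref, np.roll(row, lag)) >= np.dot(ref, row)

    def test_tmsp_alignment_brings_maxima_to_zero_ppm(self):
        shifts = [-3, 0, 5]
        s = make_series([np.roll(SIGNAL, k) for k in shifts])
        out = pp.align_to_tmsp(s)
        assert out.post_state[-1][1]["shifts"] == [-k for k in shifts]
        target = int(np.argmin(np.abs(PPM)))
        window = (PPM >= -0.3) & (PPM <= 0.3)
        for row in out.matrix:
            masked = np.where(window, row, -np.inf)
            assert int(np.argmax(masked)) == target

    def test_missing_tmsp_names_the_spectrum(self):
        flat = np.zeros(N_POINTS)
        s = make_series([SIGNAL, flat])
        with pytest.raises(ValueError, match="spectrum 1"):
            pp.align_to_tmsp(s)

    def test_recorded_shifts_replay_to_same_output(self):
        shifts = [-4, 2, 9]
        s = make_series([np.roll(SIGNAL, k) for k in shifts])
        out = pp.align_to_reference(s, 0)
        rec = out.post_state[-1][1]["shifts"]
        replay = np.vstack([np.roll(s.matrix[i], rec[i]) for i in range(3)])
        np.testing.assert_array_equal(replay, out.matrix)


class TestScaling:
    def test_total_area_scales_to_unit_sum_and_is_idempotent(self):
        s = make_series([SIGNAL, 2.0 * SIGNAL, 0.3 * SIGNAL])
        out = pp.scale_total_area(s)
        for row in out.matrix:
            assert np.sum(row) == pytest.approx(1.0, abs=1e-12)
        again = pp.scale_total_area(out)
        np.testing.assert_allclose(again.matrix, out.matrix, atol=1e-12)

    def test_dilution_series_collapses_to_identical_rows(self):
        out = pp.scale_total_area(make_series([SIGNAL, 2.0 * SIGNAL]))
        np.testing.assert_allclose(out.matrix[0], out.matrix[1], atol=1e-15)

    def test_pqn_noiseless_factors_proportional_to_dilutions(self):
        out = pp.scale_pqn(make_series([SIGNAL, 2.0 * SIGNAL, 5.0 * SIGNAL]))
        f = np.array(out.post_state[-1][1]["combined_factors"])
        np.testing.assert_allclose(f / f[0], [1.0, 2.0, 5.0], rtol=1e-10)
        np.testing.assert_allclose(out.matrix[0], out.matrix[2], atol=1e-12)

    def test_pqn_rejects_single_spectrum(self):
        with pytest.raises(ValueError, match="2"):
            pp.scale_pqn(make_series([SIGNAL]))

    def test_tmsp_scaling_equalises_analyte_rows(self):
        tmsp_a = gaussian_peak(0.0, 0.01, 30.0)
        analyte = gaussian_peak(3.0, 0.02, 50.0)
        s = make_series([analyte + tmsp_a, analyte + 2.0 * tmsp_a])
        out = pp.scale_to_tmsp(s)
        f = out.post_state[-1][1]["factors"]
        assert f[1] / f[0] == pytest.approx(2.0, rel=1e-6)

    def test_tmsp_scaling_missing_peak_rejected(self):
        s = make_series([gaussian_peak(3.0, 0.02, 50.0) - 1e-6])
        with pytest.raises(ValueError, match="TMSP"):
            pp.scale_to_tmsp(s)


class TestGlog:
    def test_analytic_values(self):
        assert pp.glog(0.0, 1.0) == pytest.approx(0.0, abs=1e-12)
        assert pp.glog(1.0, 1e-12) == pytest.approx(np.log(2.0), abs=1e-6)

    @given(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3),
           st.floats(1e-6, 1e6))
    def test_strictly_increasing_in_x(self, x1, x2, lam):
        lo, hi = sorted((x1, x2))
        if hi - lo < 1e-6 * (1.0 + abs(lo) + abs(hi)):
            return  # below float resolution of the transform
        assert pp.glog(lo, lam) < pp.glog(hi, lam)

    def test_grid_argmax_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        mat = np.abs(rng.normal(1.0, 0.5, (8, 400)))
        s = SpectrumSeries(mat, np.linspace(10, -1, 400))
        grid = np.logspace(-8, 2, 51)
        result = pp.optimize_glog_lambda(s, grid)

        # independent brute force: same objective written from its definition
        def objective(lam):
            y = np.log(mat + np.sqrt(mat * mat + lam))
            y = y / y.sum()
            return sum(float(np.var(y[:, j])) for j in range(y.shape[1]))

        best = max(grid, key=objective)
        lo = grid[max(0, int(np.where(grid == best)[0][0]) - 1)]
        hi = grid[min(len(grid) - 1, int(np.where(grid == best)[0][0]) + 1)]
        assert lo <= result.lam <= hi
        assert objective(result.lam) >= objective(best) - 1e-15

    def test_constant_matrix_rejected(self):
        s = SpectrumSeries(np.full((3, 100), 2.0), np.linspace(5, -1, 100))
        with pytest.raises(ValueError, match="constant"):
            pp.optimize_glog_lambda(s)


class TestColumnScaling:
    def test_autoscale_columns_standardised(self):
        rng = np.random.default_rng(2)
        s = make_series(rng.normal(3.0, 2.0, (10, N_POINTS)))
        out = pp.autoscale(s)
        np.testing.assert_allclose(out.matrix.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.matrix.std(axis=0), 1.0, atol=1e-12)

    def test_pareto_square_roots_the_sd(self):
        col = np.array([1.0, 9.0])  # sd 4
        s = SpectrumSeries(np.column_stack([col] * 5), np.linspace(5, -1, 5))
        out = pp.pareto(s)
        np.testing.assert_allclose(out.matrix.std(axis=0), 2.0, atol=1e-12)

    def test_identical_spectra_warn_on_all_columns(self):
        s = make_series([SIGNAL, SIGNAL.copy()])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = pp.autoscale(s)
        np.testing.assert_allclose(out.matrix, 0.0, atol=1e-12)


class TestBucket:
    def test_uniform_spectrum_full_buckets(self):
        ppm = np.linspace(10.0, 0.001, 10000)  # step 0.001 ppm (descending)
        s = SpectrumSeries(np.ones((2, 10000)), ppm)
        out = pp.bucket(s, 0.05)
        assert out.matrix[0][1] == pytest.approx(50.0)

    def test_bucket_sums_conserve_included_intensity(self):
        rng = np.random.default_rng(3)
        s = make_series(rng.normal(size=(3, N_POINTS)))
        s = pp.exclude_regions(s, [(4.5, 5.2)])
        out = pp.bucket(s, 0.04)
        included_total = s.matrix[:, s.included_mask].sum()
        assert out.matrix.sum() == pytest.approx(included_total, rel=1e-12)

    def test_brute_force_bucket_sums_match(self):
        rng = np.random.default_rng(5)
        s = make_series(rng.normal(size=(1, N_POINTS)))
        out = pp.bucket(s, 0.1)
        step = abs(PPM[1] - PPM[0])
        per = int(round(0.1 / step))
        brute = [s.matrix[0][i:i + per].sum() for i in range(0, N_POINTS, per)]
        np.testing.assert_allclose(np.sort(out.matrix[0]), np.sort(brute),
                                   rtol=1e-12)

    def test_excluded_water_region_produces_no_bucket_mass(self):
        s = pp.exclude_regions(make_series([SIGNAL]), [(4.5, 5.2)])
        out = pp.bucket(s, 0.05)
        assert not np.any((out.ppm >= 4.52) & (out.ppm <= 5.18))

    def test_width_below_grid_step_rejected(self):
        with pytest.raises(ValueError, match="width"):
            pp.bucket(make_series([SIGNAL]), 1e-5)


class TestReconstructability:
    def test_post_state_records_every_step(self):
        s = make_series([SIGNAL + 0.1, 2.0 * SIGNAL + 0.1])
        s = pp.exclude_regions(s, [(4.5, 5.2)])
        s = pp.scale_total_area(s)
        s = pp.glog_transform(s, pp.GlogParams(1e-4))
        ops = [op for op, _ in s.post_state]
        assert ops == ["exclude_regions", "scale_total_area", "glog_transform"]

    def test_replaying_post_state_reproduces_matrix_bit_exactly(self):
        raw = make_series([SIGNAL + 0.1, 2.0 * SIGNAL + 0.1, 1.3 * SIGNAL + 0.1])
        s = pp.exclude_regions(raw, [(4.5, 5.2)])
        s = pp.scale_total_area(s)
        s = pp.align_to_reference(s, 0)
        s = pp.glog_transform(s, pp.GlogParams(2e-5))
        replay = raw.copy()
        from nmrproc.pipeline import _apply_series_step
        for op, params in s.post_state:
            if op == "exclude_regions":
                replay = pp.exclude_regions(replay, params["regions"])
            elif op == "scale_total_area":
                replay = pp.scale_total_area(replay)
            elif op == "align_to_reference":
                replay = pp.align_to_reference(replay, params["ref_index"],
                                               params["max_shift"])
            elif op == "glog_transform":
                replay = pp.glog_transform(replay, pp.GlogParams(params["lam"],
                                                                 params["y0"]))
        np.testing.assert_array_equal(replay.matrix, s.matrix)
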