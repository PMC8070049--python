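"""Unit and property tests for the broken-line regression engine."""

import numpy as np
import pytest

from cogspan.segmented import (
    davies_test,
    fit_segmented,
    peak_from_fit,
    predict,
    select_n_breakpoints,
    side_slope,
)

from conftest import one_break_data, profile_rss_grid


class TestFitSegmented:
    def test_noiseless_piecewise_line_recovered_exactly(self):
        x = np.arange(0.0, 20.01, 0.5)
        y = np.where(x <= 10, 1 + 0.5 * x, 6 - 0.2 * (x - 10))
        fit = fit_segmented(x, y, 1)
        assert fit.converged
        assert fit.psi[0] == pytest.approx(10.0, abs=1e-6)
        assert fit.segment_slopes[0] == pytest.approx(0.5, abs=1e-6)
        assert fit.segment_slopes[1] == pytest.approx(-0.2, abs=1e-6)

    def test_matches_dense_grid_profile_least_squares(self, rng):
        x, y = one_break_data(rng, n=200)
        fit = fit_segmented(x, y, 1)
        rss_grid, psi_grid = profile_rss_grid(x, y)
        assert fit.psi[0] == pytest.approx(psi_grid, abs=0.05)
        rss_fit = fit.resid_var * fit.n
        assert rss_fit <= rss_grid * (1 + 1e-6)

    def test_zero_breakpoints_is_ordinary_regression(self, rng):
        x = rng.uniform(0, 10, 100)
        y = 2.0 + 0.3 * x + rng.normal(0, 0.5, 100)
        fit = fit_segmented(x, y, 0)
        coef = np.polyfit(x, y, 1)
        assert fit.segment_slopes[0] == pytest.approx(coef[0], abs=1e-10)
        assert fit.intercept == pytest.approx(coef[1], abs=1e-10)
        assert fit.n_breakpoints == 0 and fit.psi.size == 0

    def test_slope_change_identity_and_psi_ordering(self, rng):
        x = rng.uniform(12, 69, 4000)
        y = (0.15 * x - 0.13 * np.maximum(x - 17, 0)
             - 0.03 * np.maximum(x - 28, 0) + rng.normal(0, 1, 4000))
        fit = fit_segmented(x, y, 2)
        assert np.all(np.diff(fit.psi) > 0)
        assert np.all((fit.psi > x.min()) & (fit.psi < x.max()))
        np.testing.assert_allclose(
            fit.slope_changes, np.diff(fit.segment_slopes), atol=1e-10
        )

    def test_shift_and_scale_invariance(self, rng):
        x, y = one_break_data(rng, n=500)
        base = fit_segmented(x, y, 1)
        shifted = fit_segmented(x + 30.0, y, 1)
        scaled = fit_segmented(x, 2.5 * y, 1)
        assert shifted.psi[0] == pytest.approx(base.psi[0] + 30.0, abs=1e-4)
        np.testing.assert_allclose(
            scaled.segment_slopes, 2.5 * base.segment_slopes, rtol=1e-4
        )

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_segmented(np.arange(8.0), np.arange(8.0), 1)


def test_agrees_with_reference_broken_line_implementation(tmp_path, rng):
    """At clean signal-to-noise our fit and R's 'segmented' package land on
    the same breakpoint and slopes (both may differ on very noisy data,
    where the local R iteration can stop short of the profile optimum)."""
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not on PATH")
    x = rng.uniform(12, 69, 2000)
    y = 0.04 * x - 0.06 * np.maximum(x - 20.5, 0) + rng.normal(0, 0.3, 2000)
    csv = tmp_path / "d.csv"
    np.savetxt(csv, np.column_stack([x, y]), delimiter=",",
               header="x,y", comments="")
    script = tmp_path / "fit.R"
    script.write_text(
        "suppressMessages(library(segmented))\n"
        f'd <- read.csv("{csv}")\n'
        "m <- lm(y ~ x, data=d)\n"
        "s <- segmented(m, seg.Z=~x, npsi=1)\n"
        'cat(s$psi[,"Est."], coef(s)[["x"]], slope(s)$x[2,1], "\\n")\n'
    )
    proc = subprocess.run(["Rscript", str(script)], capture_output=True,
                          text=True)
    if proc.returncode != 0:
        pytest.skip(f"reference implementation unavailable: {proc.stderr}")
    psi_r, slope1_r, slope2_r = map(float, proc.stdout.split())
    fit = fit_segmented(x, y, 1)
    assert fit.psi[0] == pytest.approx(psi_r, abs=0.1)
    assert fit.segment_slopes[0] == pytest.approx(slope1_r, rel=0.02)
    assert fit.segment_slopes[1] == pytest.approx(slope2_r, rel=0.02)


class TestPredict:
    @pytest.fixture()
    def fit(self, rng):
        x, y = one_break_data(rng, n=300)
        return fit_segmented(x, y, 1)

    def test_continuity_at_breakpoint(self, fit):
        p = fit.psi[0]
        eps = 1e-9
        left, right = predict(fit, [p - eps, p + eps])
        assert abs(left - right) < 1e-6  # O(eps * slope_change)
        exact = predict(fit, [p])
        assert abs(exact[0] - left) < 1e-6

    def test_piecewise_linear_between_breakpoints(self, fit):
        grid = np.linspace(*fit.x_range, 400)
        vals = predict(fit, grid)
        d2 = np.diff(vals, 2)
        h = grid[1] - grid[0]
        near_psi = np.abs(grid[1:-1] - fit.psi[0]) < 2 * h
        assert np.all(np.abs(d2[~near_psi]) < 1e-9)
        assert np.any(np.abs(d2[near_psi]) > 1e-6)


class TestSelection:
    def test_linear_data_selects_zero_breakpoints(self, rng):
        hits = 0
        for _ in range(20):
            x = rng.uniform(12, 69, 1000)
            y = 0.01 * x + rng.normal(0, 1, 1000)
            best, _ = select_n_breakpoints(x, y, 3)
            hits += best.n_breakpoints == 0
        assert hits >= 18

    def test_bic_table_shape_and_unique_minimum(self, rng):
        x, y = one_break_data(rng, n=2000, noise=0.3)
        best, table = select_n_breakpoints(x, y, 3)
        assert 1 <= len(table) <= 4
        bics = [row["bic"] for row in table]
        assert best.bic == min(bics)
        assert bics.count(min(bics)) == 1

    def test_selection_accuracy_grows_with_sample_size(self, rng):
        rates = {}
        for n in (500, 13444):
            hits = 0
            for _ in range(10):
                x = rng.uniform(12, 69, n)
                y = (0.036 * x - 0.059 * np.maximum(x - 20.42, 0)
                     + rng.normal(0, 1, n))
                best, _ = select_n_breakpoints(x, y, 2)
                hits += best.n_breakpoints == 1
            rates[n] = hits / 10
        assert rates[13444] >= rates[500]
        assert rates[13444] >= 0.8


class TestDavies:
    def test_detects_strong_slope_change(self, rng):
        x = rng.uniform(12, 69, 9451)
        y = 0.04 * x - 0.06 * np.maximum(x - 20, 0) + rng.normal(0, 1, 9451)
        _, p = davies_test(x, y)
        assert p < 0.001

    def test_p_nonincreasing_in_slope_change(self, rng):
        x = rng.uniform(12, 69, 2000)
        noise = rng.normal(0, 1, 2000)
        pvals = []
        for delta in (0.0, -0.01, -0.02, -0.04, -0.08):
            y = 0.03 * x + delta * np.maximum(x - 30, 0) + noise
            pvals.append(davies_test(x, y)[1])
        assert all(a >= b - 1e-12 for a, b in zip(pvals, pvals[1:]))

    def test_perfect_linear_fit_returns_one(self):
        x = np.linspace(0, 50, 60)
        with pytest.warns(UserWarning, match="perfect linear"):
            stat, p = davies_test(x, 2.0 + 0.1 * x)
        assert p == 1.0


class TestPeakAndSlopes:
    def test_peak_at_breakpoint_for_rise_then_fall(self, rng):
        x, y = one_break_data(rng, n=1000, psi=10.0, slopes=(0.5, -0.2))
        fit = fit_segmented(x, y, 1)
        peak = peak_from_fit(fit)
        assert peak.peak_age == pytest.approx(fit.psi[0])
        assert not peak.at_boundary and peak.which_breakpoint == 0

    def test_peak_at_second_breakpoint_for_two_rises_then_fall(self, rng):
        x = rng.uniform(12, 69, 8000)
        y = (0.146 * x - 0.131 * np.maximum(x - 17.16, 0)
             - 0.023 * np.maximum(x - 28.42, 0) + rng.normal(0, 0.25, 8000))
        fit = fit_segmented(x, y, 2, init=[17, 28])
        peak = peak_from_fit(fit)
        assert peak.which_breakpoint == 1
        assert peak.peak_age == pytest.approx(28.42, abs=2.0)

    def test_all_declining_peaks_at_lower_boundary(self, rng):
        x = rng.uniform(12, 69, 4000)
        y = (-0.014 * x - 0.015 * np.maximum(x - 38, 0)
             + rng.normal(0, 0.5, 4000))
        fit = fit_segmented(x, y, 1)
        peak = peak_from_fit(fit, age_range=(12, 69))
        assert peak.at_boundary and peak.peak_age == 12
        inc = side_slope(fit, peak, "left")
        assert not inc.defined and np.isnan(inc.value)
        dec = side_slope(fit, peak, "right")
        assert dec.combined and dec.n_segments == 2

    def test_single_segment_slope_passed_through(self, rng):
        x, y = one_break_data(rng, n=1000, psi=30.0, slopes=(0.036, -0.023),
                              span=(12.0, 69.0), noise=0.5)
        fit = fit_segmented(x, y, 1)
        peak = peak_from_fit(fit)
        inc = side_slope(fit, peak, "left")
        assert not inc.combined
        assert inc.value == pytest.approx(fit.segment_slopes[0])
        assert inc.ci[0] <= inc.value <= inc.ci[1]

    def test_combined_slope_is_length_weighted_average(self):
        # segments of 0.5 over 4 years then 0.1 over 6 years -> 0.26
        x = np.linspace(0, 12, 400)
        y = np.where(x <= 4, 0.5 * x,
                     np.where(x <= 10, 2 + 0.1 * (x - 4), 2.6 - 0.3 * (x - 10)))
        fit = fit_segmented(x, y, 2, init=[4, 10])
        peak = peak_from_fit(fit)
        inc = side_slope(fit, peak, "left")
        assert inc.combined
        assert inc.value == pytest.approx((0.5 * 4 + 0.1 * 6) / 10, abs=1e-6)

    def test_combined_slope_equals_chord_slope(self, rng):
        x = rng.uniform(12, 69, 6000)
        y = (0.15 * x - 0.13 * np.maximum(x - 17, 0)
             - 0.028 * np.maximum(x - 28, 0) + rng.normal(0, 0.5, 6000))
        fit = fit_segmented(x, y, 2, init=[17, 28])
        peak = peak_from_fit(fit)
        inc = side_slope(fit, peak, "left")
        lo = fit.x_range[0]
        chord = (predict(fit, [peak.peak_age])[0] - predict(fit, [lo])[0]) \
            / (peak.peak_age - lo)
        assert inc.value == pytest.approx(chord, abs=1e-10)
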