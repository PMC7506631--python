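"""Calibration statistics, comparison regressions, EJCR, RMSE/RSD."""

import numpy as np
import pytest
from scipy import stats

import etongue as et
from etongue.core_data import ValidationError
from etongue.evaluate import ejcr_contains
from etongue.simulator import AnalyteResponse, SensorResponseSpec


class TestPeakHeight:
    def test_flat_zero_trace(self):
        E = np.arange(5.0)
        assert et.peak_height(et.Voltammogram("s", E, np.zeros(5))) == 0.0

    def test_explicit_maximum(self):
        E = np.arange(5.0)
        v = et.Voltammogram("s", E, np.array([0.0, 1.0, 3.0, 2.0, 0.0]))
        assert et.peak_height(v) == 3.0

    def test_blank_subtraction_recovers_amplitude(self):
        program = et.PotentialProgram(-0.7, 1.2, 0.01, 381)
        spec = SensorResponseSpec(
            "s", {"PA": AnalyteResponse(0.0598, 0.39, 0.15)},
            baseline_slope_uA_per_V=1.1, baseline_offset_uA=0.6,
        )
        v = et.simulate_voltammogram(spec, {"PA": 100.0}, program)
        blank = et.simulate_voltammogram(spec, {"PA": 0.0}, program)
        assert et.peak_height(v, blank) == pytest.approx(5.98, rel=1e-10)

    def test_grid_mismatch_rejected(self):
        a = et.Voltammogram("s", np.arange(5.0), np.zeros(5))
        b = et.Voltammogram("s", np.arange(5.0) + 1, np.zeros(5))
        with pytest.raises(ValidationError):
            et.peak_height(a, b)


class TestFitCalibration:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = et.fit_calibration(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.s_yx == pytest.approx(0.0, abs=1e-12)
        assert fit.lod_uM == pytest.approx(0.0, abs=1e-12)

    def test_matches_reference_least_squares(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        x = rng.uniform(0, 500, 12)
        y = 0.05 * x + 1.0 + rng.normal(0, 0.5, 12)
        fit = et.fit_calibration(x, y)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.slope == pytest.approx(ref.params[1], rel=1e-10)
        assert fit.intercept == pytest.approx(ref.params[0], rel=1e-10)
        assert fit.s_yx == pytest.approx(np.sqrt(ref.mse_resid), rel=1e-10)
        assert fit.lod_uM == pytest.approx(3 * np.sqrt(ref.mse_resid) / ref.params[1], rel=1e-10)

    def test_simulated_zno_calibration_recovers_published_slope(self):
        """Noise-free calibration of a 0.0598 µA/µM sensor returns that slope."""
        program = et.PotentialProgram(-0.7, 1.2, 0.01, 381)
        spec = SensorResponseSpec(
            "ZnO", {"PA": AnalyteResponse(0.0598, 0.39, 0.15)},
            baseline_slope_uA_per_V=0.9, baseline_offset_uA=0.613,
        )
        conc = np.linspace(0, 500, 6)
        blank = et.simulate_voltammogram(spec, {"PA": 0.0}, program)
        heights = [
            et.peak_height(et.simulate_voltammogram(spec, {"PA": c}, program), blank)
            for c in conc
        ]
        fit = et.fit_calibration(conc, np.array(heights), analyte="PA", sensor_id="ZnO")
        assert fit.slope == pytest.approx(0.0598, rel=1e-9)

    def test_non_positive_slope_flags_lod_undefined(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = et.fit_calibration(x, -2 * x + 10)
        assert np.isnan(fit.lod_uM)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            et.fit_calibration([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValidationError):
            et.fit_calibration([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCompareRegression:
    def test_perfect_prediction(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rc = et.compare_regression(x, x)
        assert rc.slope == pytest.approx(1.0)
        assert rc.intercept == pytest.approx(0.0, abs=1e-12)
        assert rc.r_squared == pytest.approx(1.0)
        assert rc.rmse == pytest.approx(0.0, abs=1e-12)
        assert rc.contains_ideal  # degenerate region containing the estimates

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        rc = et.compare_regression(x, x + 2.5)
        assert rc.slope == pytest.approx(1.0)
        assert rc.intercept == pytest.approx(2.5)
        assert rc.rmse == pytest.approx(2.5)

    def test_confidence_intervals_match_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        x = rng.uniform(0, 100, 15)
        y = x + rng.normal(0, 5, 15)
        rc = et.compare_regression(x, y, confidence=0.95)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        lo, hi = ref.conf_int(alpha=0.05)[1]
        assert rc.slope_half_ci == pytest.approx((hi - lo) / 2, rel=1e-9)
        lo, hi = ref.conf_int(alpha=0.05)[0]
        assert rc.intercept_half_ci == pytest.approx((hi - lo) / 2, rel=1e-9)

    def test_zero_variance_expected_rejected(self):
        with pytest.raises(ValidationError):
            et.compare_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestEjcr:
    def test_perfect_fit_degenerate_region(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        rc = et.compare_regression(x, 1.2 * x + 0.5)
        assert ejcr_contains(rc, (1.2, 0.5)).inside
        assert not ejcr_contains(rc, (1.0, 0.0)).inside

    def test_agrees_with_quadratic_form_oracle(self):
        """Membership matches a from-definitions recomputation on a grid
        of candidate (slope, intercept) points."""
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(5, 15))
            x = rng.uniform(0, 50, n)
            y = x + rng.normal(0, 3, n)
            rc = et.compare_regression(x, y, confidence=0.95)
            # oracle quantities recomputed independently
            X = np.vstack([np.ones(n), x]).T
            beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            s2 = float(res[0]) / (n - 2)
            thresh = 2 * s2 * stats.f.ppf(0.95, 2, n - 2)
            for slope0 in np.linspace(0.5, 1.5, 5):
                for int0 in np.linspace(-10, 10, 5):
                    da, db = beta[0] - int0, beta[1] - slope0
                    q = n * da**2 + 2 * x.sum() * da * db + (x**2).sum() * db**2
                    assert ejcr_contains(rc, (slope0, int0)).inside == (q <= thresh)

    def test_monotone_in_confidence(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 50, 10)
        y = x + rng.normal(0, 2, 10)
        rc = et.compare_regression(x, y)
        for point in [(1.0, 0.0), (1.1, 1.0), (0.9, -2.0)]:
            if ejcr_contains(rc, point, 0.90).inside:
                assert ejcr_contains(rc, point, 0.95).inside

    def test_too_few_points_rejected(self):
        rc = et.compare_regression([1.0, 2.0, 3.0], [1.1, 2.0, 2.9])
        with pytest.raises(ValidationError):
            ejcr_contains(rc, (1.0, 0.0))


class TestNrmse:
    def test_perfect_prediction_is_zero(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        per, total = et.nrmse(x, x)
        assert np.allclose(per, 0.0) and total == 0.0

    def test_unit_case(self):
        per, total = et.nrmse(np.array([[1.0], [1.0]]), np.array([[0.0], [0.0]]))
        assert total == pytest.approx(1.0)
        assert per[0] == pytest.approx(1.0)

    def test_matches_definition_on_random_matrices(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 100, size=(11, 3))
        y = x + rng.normal(0, 5, x.shape)
        per, total = et.nrmse(x, y)
        assert np.allclose(per, np.sqrt(np.mean((y - x) ** 2, axis=0)))
        assert total == pytest.approx(np.sqrt(np.sum((y - x) ** 2) / np.sum(x**2)))

    def test_all_zero_expected_rejected(self):
        with pytest.raises(ValidationError):
            et.nrmse(np.zeros((3, 2)), np.ones((3, 2)))


class TestRepeatabilityRsd:
    def test_constant_vector_is_zero(self):
        assert et.repeatability_rsd([5.0, 5.0, 5.0]) == 0.0

    def test_hand_computed_case(self):
        assert et.repeatability_rsd([9.0, 11.0]) == pytest.approx(
            100 * np.sqrt(2) / 10
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(ValidationError):
            et.repeatability_rsd([-1.0, 1.0])

    def test_consecutive_measurements_stay_below_4pct(self):
        """18 replicate peak heights at 2%-of-signal noise give RSD < 4%,
        the conventional stability acceptance bound."""
        program = et.PotentialProgram(-0.7, 1.2, 0.01, 381)
        spec = SensorResponseSpec(
            "s", {"PA": AnalyteResponse(0.06, 0.39, 0.15)},
            noise_sd_uA=0.02 * 0.06 * 100.0,  # 2% of the 100 µM signal
        )
        rng = np.random.default_rng(5)
        blank = et.simulate_voltammogram(
            SensorResponseSpec("s", {"PA": AnalyteResponse(0.0, 0.39, 0.15)}),
            {"PA": 0.0}, program,
        )
        heights = [
            et.peak_height(
                et.simulate_voltammogram(spec, {"PA": 100.0}, program, rng=rng), blank
            )
            for _ in range(18)
        ]
        assert et.repeatability_rsd(heights) < 4.0
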