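"""Calibration and agreement statistics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from abdomct import (
    bland_altman_pct,
    categorize_agreement,
    categorize_correlation,
    fit_calibration,
    lins_ccc,
    predict_mass,
    reliability_agreement,
    validate_thresholds,
)
from abdomct.composition import final_validation_rows
from abdomct.errors import DegenerateInputError
from abdomct.synthetic_data import (
    cohort_frames_for_validation,
    default_cohort_params,
    simulate_cohort,
)


def ols_closed_form(x, y):
    """Independent normal-equations OLS with t-based 95% CIs."""
    import scipy.stats

    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    sxx = ((x - x.mean()) ** 2).sum()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - slope * x - intercept
    s2 = (resid**2).sum() / (n - 2)
    se_slope = np.sqrt(s2 / sxx)
    se_icpt = np.sqrt(s2 * (1 / n + x.mean() ** 2 / sxx))
    t = scipy.stats.t.ppf(0.975, n - 2)
    return slope, intercept, (slope - t * se_slope, slope + t * se_slope), (
        intercept - t * se_icpt,
        intercept + t * se_icpt,
    )


def ccc_direct(a, b):
    """Direct evaluation of the concordance formula with n-divisor moments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    return 2 * np.mean((a - a.mean()) * (b - b.mean())) / (
        a.var() + b.var() + (a.mean() - b.mean()) ** 2
    )


class TestFitCalibration:
    def test_noiseless_line(self):
        m = fit_calibration([1, 2, 3], [4, 7, 10])
        assert m.slope == pytest.approx(3.0)
        assert m.intercept == pytest.approx(1.0)
        assert m.r_squared == pytest.approx(1.0)

    def test_matches_closed_form_normal_equations(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(1, 18, 30)
        y = 3.46 * x + 0.02 + rng.normal(0, 1.5, 30)
        m = fit_calibration(x, y)
        slope, icpt, sci, ici = ols_closed_form(x, y)
        assert m.slope == pytest.approx(slope, abs=1e-10)
        assert m.intercept == pytest.approx(icpt, abs=1e-10)
        assert m.slope_ci == pytest.approx(sci, abs=1e-8)
        assert m.intercept_ci == pytest.approx(ici, abs=1e-8)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 10, 12)
        y = 2 * x + rng.normal(0, 1, 12)
        m = fit_calibration(x, y)
        assert m.slope_ci[0] <= m.slope <= m.slope_ci[1]
        assert m.intercept_ci[0] <= m.intercept <= m.intercept_ci[1]

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_calibration([1, 2], [1, 2])

    def test_constant_x_is_singular(self):
        with pytest.raises(DegenerateInputError):
            fit_calibration([2, 2, 2], [1, 2, 3])

    def test_residuals_sum_to_zero_and_mean_prediction(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(1, 15, 25)
        y = 5.22 * x - 2.80 + rng.normal(0, 2, 25)
        m = fit_calibration(x, y)
        resid = y - predict_mass(m, x)
        assert abs(resid.sum()) <= 1e-9 * np.abs(y).sum()
        assert predict_mass(m, float(x.mean())) == pytest.approx(y.mean())


class TestPredictMass:
    def test_published_coefficients_arithmetic(self):
        """Slope 3.46 kg/L, intercept 0.02 kg at 10 L → 34.62 kg."""
        from abdomct.method_stats import CalibrationModel

        m = CalibrationModel(3.46, 0.02, (3.26, 3.65), (-1.44, 1.49), 0.985, 22)
        assert predict_mass(m, 10.0) == pytest.approx(34.62)
        assert predict_mass(m, 0.0) == pytest.approx(0.02)

    def test_negative_volume_rejected(self):
        from abdomct.method_stats import CalibrationModel

        m = CalibrationModel(1.0, 0.0, (0.9, 1.1), (-0.1, 0.1), 1.0, 3)
        with pytest.raises(ValueError):
            predict_mass(m, -1.0)


class TestLinsCCC:
    def test_identical_sequences_are_perfectly_concordant(self):
        res = lins_ccc([1.0, 2.0, 5.0, 3.0], [1.0, 2.0, 5.0, 3.0])
        assert res.rc == pytest.approx(1.0)
        assert res.ci[1] <= 1.0

    def test_worked_example_four_sevenths(self):
        res = lins_ccc([1, 2, 3], [2, 3, 4])
        assert res.rc == pytest.approx(4 / 7, abs=1e-10)

    def test_matches_direct_formula_on_random_data(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            a = rng.normal(10, 3, 20)
            b = 0.8 * a + rng.normal(0, 1.5, 20)
            res = lins_ccc(a, b)
            assert res.rc == pytest.approx(ccc_direct(a, b), abs=1e-10)

    @given(st.integers(0, 10**6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_concordance_never_exceeds_correlation(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 2, 15)
        res = lins_ccc(a, b)
        assert abs(res.rc) <= abs(res.pearson_r) + 1e-12
        assert -1 <= res.rc <= 1
        assert res.ci[0] <= res.rc <= res.ci[1]

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            lins_ccc([1, 1, 1], [1, 2, 3])


class TestBlandAltman:
    def test_identical_inputs_zero_bias_zero_loa(self):
        res = bland_altman_pct([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias_pct == 0
        assert res.loa_low_pct == 0 and res.loa_high_pct == 0

    def test_hand_worked_pair_example(self):
        """(102,98) and (98,102): ±4% differences, sd 5.6569, LOA ∓11.0874."""
        res = bland_altman_pct([102, 98], [98, 102])
        assert res.bias_pct == pytest.approx(0.0, abs=1e-12)
        assert res.sd_pct == pytest.approx(np.sqrt(32), abs=1e-4)
        assert res.loa_high_pct == pytest.approx(11.0874, abs=1e-3)
        assert res.loa_low_pct == pytest.approx(-11.0874, abs=1e-3)

    def test_loa_reconstruct_from_bias_and_sd(self):
        rng = np.random.default_rng(13)
        m = rng.uniform(5, 50, 22)
        r = m * rng.normal(1, 0.05, 22)
        res = bland_altman_pct(m, r)
        assert res.loa_low_pct == res.bias_pct - 1.96 * res.sd_pct
        assert res.loa_high_pct == res.bias_pct + 1.96 * res.sd_pct

    def test_swapping_roles_negates_bias(self):
        rng = np.random.default_rng(14)
        m = rng.uniform(5, 50, 10)
        r = m * rng.normal(1, 0.03, 10)
        assert bland_altman_pct(m, r).bias_pct == pytest.approx(-bland_altman_pct(r, m).bias_pct)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman_pct([1.0], [1.0])

    def test_zero_pair_mean_names_index(self):
        with pytest.raises(DegenerateInputError, match="1"):
            bland_altman_pct([1.0, 1.0], [1.0, -1.0])

    def test_reference_denominator_option(self):
        res = bland_altman_pct([102.0, 51.0], [100.0, 50.0], denominator="reference")
        assert res.bias_pct == pytest.approx(2.0)


@pytest.mark.parametrize(
    "r,label",
    [
        (1.00, "perfect"),
        (0.95, "very strong"),
        (0.90, "very strong"),
        (0.80, "strong"),
        (0.70, "strong"),
        (0.60, "moderate"),
        (0.40, "poor"),
        (0.10, "negligible"),
        (-0.95, "very strong"),
    ],
)
def test_categorize_correlation(r, label):
    assert categorize_correlation(r) == label


@pytest.mark.parametrize(
    "cl,label",
    [
        (1.000, "perfect"),
        (0.998, "near perfect"),
        (0.990, "near perfect"),
        (0.982, "substantial"),
        (0.950, "substantial"),
        (0.920, "moderate"),
        (0.879, "poor"),
    ],
)
def test_categorize_agreement(cl, label):
    assert categorize_agreement(cl) == label


class TestReliabilityAgreement:
    def test_identical_repeats(self):
        a = np.array([1.1, 2.3, 3.7, 0.9, 5.5])
        cc, ba = reliability_agreement(a, a)
        assert cc.rc == pytest.approx(1.0)
        assert ba.bias_pct == 0

    def test_constant_multiplicative_offset(self):
        """+2% repeats → bias 100·0.02/1.01 ≈ 1.9802% under the pair-mean denominator."""
        a = np.array([1.0, 2.0, 4.0, 8.0])
        cc, ba = reliability_agreement(1.02 * a, a)
        assert ba.bias_pct == pytest.approx(100 * 0.02 / 1.01, abs=1e-10)
        assert ba.sd_pct == pytest.approx(0.0, abs=1e-9)

    def test_composes_the_underlying_operations(self):
        rng = np.random.default_rng(31)
        a = rng.uniform(0.5, 4, 12)
        b = a * rng.normal(1, 0.02, 12)
        cc, ba = reliability_agreement(b, a)
        assert cc.rc == pytest.approx(lins_ccc(b, a).rc)
        assert ba.bias_pct == pytest.approx(bland_altman_pct(b, a).bias_pct)


class TestValidateThresholds:
    def _noiseless_frames(self):
        params = default_cohort_params(seed=5)
        params = type(params)(
            **{
                **{f: getattr(params, f) for f in params.__dataclass_fields__},
                "noise_sd": {c: 0.0 for c in params.noise_sd},
            }
        )
        return cohort_frames_for_validation(simulate_cohort(params))

    def test_noiseless_cohort_is_perfect(self):
        volumes, dxa = self._noiseless_frames()
        report = validate_thresholds(volumes, dxa, rows=final_validation_rows())
        for row in report.rows:
            assert row.calibration.r_squared == pytest.approx(1.0)
            assert row.concordance.rc == pytest.approx(1.0)
            assert row.bland_altman.bias_pct == pytest.approx(0.0, abs=1e-8)
            assert row.agreement_label == "perfect"

    def test_rows_equal_component_operations(self):
        cohort = simulate_cohort(default_cohort_params(seed=9))
        volumes, dxa = cohort_frames_for_validation(cohort)
        report = validate_thresholds(volumes, dxa, rows=final_validation_rows())
        row = next(r for r in report.rows if r.component == "total")
        v = np.array([d.volumes_l["total"] for d in cohort])
        m = np.array([d.dxa.total_mass for d in cohort])
        cal = fit_calibration(v, m)
        pred = predict_mass(cal, v)
        assert row.calibration.slope == pytest.approx(cal.slope)
        assert row.concordance.rc == pytest.approx(lins_ccc(pred, m).rc)
        assert row.bland_altman.bias_pct == pytest.approx(bland_altman_pct(pred, m).bias_pct)

    def test_full_report_carries_literature_and_excluded_rows(self):
        volumes, dxa = self._noiseless_frames()
        report = validate_thresholds(volumes, dxa)
        frame = report.to_frame()
        canine = frame[(frame["component"] == "fat") & (frame["range"] == "-135/-105")]
        assert len(canine) == 1
        assert "canine" in canine.iloc[0]["annotation"]
        excluded = frame[frame["excluded"]]
        assert len(excluded) == 5
        assert excluded["annotation"].str.startswith("excluded").all()
        assert "slope" not in excluded.columns or excluded["slope"].isna().all()

    def test_subject_mismatch_lists_offenders(self):
        volumes, dxa = self._noiseless_frames()
        dxa = dxa[dxa["subject"] != "dog03"]
        with pytest.raises(ValueError, match="dog03"):
            validate_thresholds(volumes, dxa)

    def test_loo_mode_differs_but_stays_close(self):
        cohort = simulate_cohort(default_cohort_params(seed=17))
        volumes, dxa = cohort_frames_for_validation(cohort)
        rows = final_validation_rows()
        in_sample = validate_thresholds(volumes, dxa, rows=rows)
        loo = validate_thresholds(volumes, dxa, rows=rows, loo=True)
        rc_in = in_sample.rows[0].concordance.rc
        rc_loo = loo.rows[0].concordance.rc
        assert rc_in != rc_loo
        assert abs(rc_in - rc_loo) < 0.05
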