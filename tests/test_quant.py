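"""Calibration, LOD/SNR/CV statistics, inversion, clinical banding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lfaquant as lq
from lfaquant.quant import CurveForm


def _curve(slope, intercept, form=CurveForm.LINEAR_C, blank_mean=0.0, blank_sd=0.0,
           valid_range=(0.0, 100.0), analyte="CEA", line_role="test"):
    return lq.CalibrationCurve(
        analyte=analyte, line_role=line_role, form=form, slope=slope,
        intercept=intercept, valid_range=valid_range, r_squared=1.0,
        residual_sd=0.0, blank_mean=blank_mean, blank_sd=blank_sd,
    )


class TestFitCalibration:
    def test_exact_line_recovered(self):
        pts = [(c, [2 * c + 1]) for c in (1.0, 2.0, 5.0, 10.0)]
        curve = lq.fit_calibration(pts, "linear_c", blanks=[1.0, 1.0])
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(1.0)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_recovers_generator_slope_within_ten_percent(self):
        """Replicate CEA-like data at 5% CV recovers the generator's local
        linear slope."""
        rng = np.random.default_rng(12)
        levels = np.linspace(5, 50, 8)
        resp = lq.CEA_RESPONSE
        pts = [
            (c, [resp.test_signal(c) * (1 + 0.05 * rng.standard_normal())
                 for _ in range(3)])
            for c in levels
        ]
        curve = lq.fit_calibration(pts, "linear_c", blanks=[0.1, 0.2, 0.15])
        # straight-line slope of the noiseless response over the same window
        truth = np.polyfit(levels, [resp.test_signal(c) for c in levels], 1)[0]
        assert curve.slope == pytest.approx(truth, rel=0.10)

    def test_decreasing_data_gives_decreasing_direction(self):
        pts = [(c, [100 - 3 * c]) for c in (1.0, 5.0, 10.0, 20.0)]
        curve = lq.fit_calibration(pts, "linear_c", blanks=[100, 99], line_role="antigen")
        assert curve.slope < 0 and curve.direction == "decreasing"

    def test_too_few_levels_rejected(self):
        with pytest.raises(lq.FitError):
            lq.fit_calibration([(1.0, [2.0]), (2.0, [3.0])], "linear_c", blanks=[0, 0])

    def test_identical_concentrations_rejected(self):
        pts = [(5.0, [1.0])] * 6
        with pytest.raises(lq.FitError):
            lq.fit_calibration(pts, "linear_c", blanks=[0, 0])

    def test_log_form_requires_positive_concentrations(self):
        pts = [(c, [c]) for c in (0.0, 1.0, 2.0, 5.0)]
        with pytest.raises(lq.FitError):
            lq.fit_calibration(pts, "linear_log10c", blanks=[0, 0])


class TestLod:
    def test_hand_inversion_of_limit_of_blank(self):
        # blank 10 +/- 2, curve y = 10 + 4c: LOD = (16 - 10)/4 = 1.5
        curve = _curve(slope=4.0, intercept=10.0, blank_mean=10.0, blank_sd=2.0)
        assert lq.lod(curve) == pytest.approx(1.5)

    def test_perfect_blank_gives_zero_lod(self):
        curve = _curve(slope=4.0, intercept=10.0, blank_mean=10.0, blank_sd=0.0)
        assert lq.lod(curve) == 0.0

    def test_lod_increases_with_blank_sd(self):
        lods = [
            lq.lod(_curve(slope=4.0, intercept=10.0, blank_mean=10.0, blank_sd=sd))
            for sd in (1.0, 2.0, 4.0)
        ]
        assert lods[0] < lods[1] < lods[2]

    def test_decreasing_curve_unsupported(self):
        with pytest.raises(ValueError):
            lq.lod(_curve(slope=-4.0, intercept=100.0))


class TestSnrAndCv:
    def test_snr_arithmetic(self):
        assert lq.snr([18, 20, 22], [16, 24, 20, 20]) == pytest.approx(
            20.0 / np.std([16, 24, 20, 20], ddof=1)
        )
        assert lq.snr([20.0, 20.0], [0.0, 8.0, 4.0]) == pytest.approx(5.0)

    def test_snr_linearity_in_signal(self):
        noise = [1.0, 3.0, 2.0]
        assert lq.snr([40.0], noise) == pytest.approx(2 * lq.snr([20.0], noise))

    def test_zero_noise_sd_rejected(self):
        with pytest.raises(ValueError):
            lq.snr([10.0], [5.0, 5.0])

    def test_cv_constant_values(self):
        assert lq.cv([10, 10, 10]) == 0.0

    def test_cv_hand_case_sample_sd(self):
        assert lq.cv([8, 10, 12]) == pytest.approx(20.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        values=st.lists(st.floats(1.0, 1e3), min_size=2, max_size=12),
        k=st.floats(0.1, 100.0),
    )
    def test_cv_scale_invariance(self, values, k):
        assert lq.cv([k * v for v in values]) == pytest.approx(
            lq.cv(values), rel=1e-9, abs=1e-9
        )

    def test_cv_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            lq.cv([-1.0, 1.0])


class TestInvertCalibration:
    def test_hand_inversion(self):
        est = lq.invert_calibration(_curve(slope=2.0, intercept=1.0), 5.0)
        assert est.value == pytest.approx(2.0)

    def test_intensity_below_blank_reports_below_lod(self):
        curve = _curve(slope=4.0, intercept=10.0, blank_mean=10.0, blank_sd=2.0)
        est = lq.invert_calibration(curve, 9.0)
        assert est.below_lod and est.text == "< LOD"
        # consistency with lod(): intensities above the LoB are quantifiable
        above = lq.invert_calibration(curve, curve.predict(2 * lq.lod(curve)))
        assert not above.below_lod

    def test_out_of_range_clamped_and_flagged(self):
        est = lq.invert_calibration(_curve(slope=1.0, intercept=0.0), 150.0)
        assert est.value == 100.0 and not est.in_range

    def test_non_finite_intensity_rejected(self):
        with pytest.raises(ValueError):
            lq.invert_calibration(_curve(slope=1.0, intercept=0.0), float("nan"))

    @pytest.mark.parametrize("form", [CurveForm.LINEAR_C, CurveForm.LINEAR_LOG10C])
    def test_roundtrip_identity_on_valid_range(self, form):
        """invert(predict(c)) = c for noiseless curves of both forms."""
        curve = _curve(
            slope=3.0 if form is CurveForm.LINEAR_C else -50.0,
            intercept=2.0 if form is CurveForm.LINEAR_C else 120.0,
            form=form, valid_range=(1.0, 100.0),
        )
        for c in (1.0, 3.0, 10.0, 31.6, 100.0):
            est_x = (curve.predict(c) - curve.intercept) / curve.slope
            c_back = 10**est_x if form is CurveForm.LINEAR_LOG10C else est_x
            assert c_back == pytest.approx(c, rel=1e-9)


class TestQuantifyCrp:
    @staticmethod
    def _curves():
        low = _curve(
            slope=28.0, intercept=12.0, form=CurveForm.LINEAR_LOG10C,
            valid_range=(1.0, 10.0), blank_mean=1.0, blank_sd=0.3,
            analyte="CRP",
        )
        high = _curve(
            slope=-68.0, intercept=180.0, form=CurveForm.LINEAR_LOG10C,
            valid_range=(10.0, 500.0), analyte="CRP", line_role="antigen",
        )
        return low, high

    def test_bright_antigen_line_selects_low_branch(self):
        low, high = self._curves()
        est = lq.quantify_crp(30.0, 140.0, low, high)
        assert est.branch == "low" and 0.0 <= est.value <= 10.0

    def test_faint_antigen_line_selects_high_branch_near_top(self):
        low, high = self._curves()
        est = lq.quantify_crp(5.0, 10.0, low, high)
        assert est.branch == "high"
        assert est.value > 100.0

    def test_continuity_across_branch_boundary(self):
        """Evaluating both branches at the 10 ug/mL crossover yields the
        same concentration for exact curves."""
        low, high = self._curves()
        at_low = lq.quantify_crp(low.predict(10.0), high.predict(10.0), low, high)
        eps = 1e-6
        at_high = lq.quantify_crp(
            low.predict(10.0), high.predict(10.0) - eps, low, high
        )
        assert at_low.branch == "low" and at_high.branch == "high"
        assert at_low.value == pytest.approx(10.0, rel=1e-6)
        assert at_high.value == pytest.approx(10.0, rel=1e-3)

    def test_both_lines_dead_is_invalid(self):
        low, high = self._curves()
        with pytest.raises(lq.InvalidTestError):
            lq.quantify_crp(0.5, 0.5, low, high)

    def test_wrong_curve_directions_rejected(self):
        low, high = self._curves()
        with pytest.raises(ValueError):
            lq.quantify_crp(10.0, 100.0, high, high)
        with pytest.raises(ValueError):
            lq.quantify_crp(10.0, 100.0, low, low)


class TestInterpretPanel:
    @pytest.mark.parametrize(
        "analyte,value,band",
        [
            ("CEA", 3.0, "normal"),
            ("CEA", 10.0, "intermediate"),
            ("CEA", 25.0, "elevated"),
            ("CA-125", 20.0, "normal"),
            ("CA-125", 60.0, "elevated"),
            ("CA-125", 120.0, "strongly_elevated"),
            ("CRP", 2.0, "low"),
            ("CRP", 50.0, "high"),
        ],
    )
    def test_banding_against_clinical_thresholds(self, analyte, value, band):
        result = lq.interpret_panel({analyte: value})
        assert result.analytes[0].band == band

    def test_all_zero_panel_is_normal_and_valid(self):
        result = lq.interpret_panel({"CEA": 0.0, "CA-125": 0.0, "CRP": 0.0})
        assert result.valid
        assert [a.band for a in result.analytes] == ["normal", "normal", "low"]

    def test_unknown_analyte_rejected(self):
        with pytest.raises(lq.ConfigError):
            lq.interpret_panel({"PSA": 1.0})

    def test_negative_concentration_rejected(self):
        with pytest.raises(lq.ConfigError):
            lq.interpret_panel({"CEA": -1.0})

    def test_thresholds_table_pinned(self):
        t = lq.quant.CLINICAL_THRESHOLDS
        assert t["CEA"]["normal_below"] == 5.0
        assert t["CEA"]["elevated_above"] == 20.0
        assert t["CA-125"]["normal_upto"] == 35.0
        assert t["CA-125"]["strongly_elevated_above"] == 100.0
        assert t["CRP"]["boundary"] == 10.0
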