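import pytest
from hypothesis import given, settings, strategies as st

from qtcdx import (GradingInput, GradingThresholds, QtcStatus, Sex, ctcae_grade,
                   sex_status, tdp_relative_risk)
from qtcdx.errors import ParameterError
from qtcdx.grading import GradeRule


class TestCtcaeGrade:
    @pytest.mark.parametrize("qtcf,expected", [
        (440, 0), (449.9, 0), (450, 1), (465, 1), (480, 1), (480.5, 1),
        (481, 2), (490, 2), (500, 2), (500.1, 3), (505, 3), (600, 3),
    ])
    def test_bands(self, qtcf, expected):
        assert ctcae_grade(GradingInput(qtcf_mean_ms=qtcf)).grade == expected

    def test_baseline_delta_rule(self):
        d = ctcae_grade(GradingInput(qtcf_mean_ms=470, baseline_qtcf_ms=400))
        assert d.grade == 3
        assert d.triggered_rule is GradeRule.BASELINE_DELTA
        assert d.delta_ms == pytest.approx(70.0)
        # exactly 60 ms is not "more than 60"
        assert ctcae_grade(GradingInput(qtcf_mean_ms=440, baseline_qtcf_ms=380)).grade == 0

    def test_baseline_decrease_does_not_trigger(self):
        assert ctcae_grade(GradingInput(qtcf_mean_ms=430, baseline_qtcf_ms=520)).grade == 0

    def test_tdp_flag_dominates(self):
        d = ctcae_grade(GradingInput(qtcf_mean_ms=420, tdp_or_serious_arrhythmia=True))
        assert d.grade == 4
        assert d.triggered_rule is GradeRule.TDP_ARRHYTHMIA

    def test_grade_rule_consistency(self):
        d = ctcae_grade(GradingInput(qtcf_mean_ms=440))
        assert d.grade == 0 and d.triggered_rule is GradeRule.NORMAL

    @given(q=st.floats(300, 600))
    @settings(max_examples=200, derandomize=True)
    def test_every_value_maps_to_exactly_one_band(self, q):
        d = ctcae_grade(GradingInput(qtcf_mean_ms=q))
        assert d.grade in (0, 1, 2, 3)
        # band membership is consistent with the grade
        expected = 3 if q > 500 else 2 if q >= 481 else 1 if q >= 450 else 0
        assert d.grade == expected

    @given(q=st.floats(300, 590), step=st.floats(0, 10))
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_qtcf(self, q, step):
        g1 = ctcae_grade(GradingInput(qtcf_mean_ms=q)).grade
        g2 = ctcae_grade(GradingInput(qtcf_mean_ms=q + step)).grade
        assert g2 >= g1

    def test_threshold_override_must_be_ordered(self):
        with pytest.raises(ParameterError):
            GradingThresholds(band1_low=500, band2_low=450)


class TestSexStatus:
    @pytest.mark.parametrize("qtcf,sex,expected", [
        (425, "male", QtcStatus.NORMAL),
        (440, "male", QtcStatus.BORDERLINE),
        (455, "male", QtcStatus.PROLONGED),
        (445, "female", QtcStatus.NORMAL),
        (460, "female", QtcStatus.BORDERLINE),
        (475, "female", QtcStatus.PROLONGED),
    ])
    def test_thresholds(self, qtcf, sex, expected):
        assert sex_status(qtcf, sex) is expected

    def test_status_omitted_without_sex(self):
        assert ctcae_grade(GradingInput(qtcf_mean_ms=440)).status is None
        assert ctcae_grade(GradingInput(qtcf_mean_ms=440, sex=Sex.MALE)).status \
            is QtcStatus.BORDERLINE


class TestTdpRisk:
    def test_zero_at_reference(self):
        assert tdp_relative_risk(440.0) == (0.0, 0.0)

    def test_one_step(self):
        lo, hi = tdp_relative_risk(450.0)
        assert lo == pytest.approx(0.05)
        assert hi == pytest.approx(0.07)

    def test_printed_worked_example(self):
        lo, hi = tdp_relative_risk(540.0)
        assert lo == pytest.approx(0.629, abs=5e-4)
        assert hi == pytest.approx(0.967, abs=5e-4)

    def test_below_reference_rejected(self):
        with pytest.raises(ParameterError):
            tdp_relative_risk(430.0)

    @given(d1=st.floats(0, 80), d2=st.floats(0, 80))
    @settings(max_examples=100, derandomize=True)
    def test_multiplicative_over_increments(self, d1, d2):
        lo12, _ = tdp_relative_risk(440 + d1 + d2)
        lo1, _ = tdp_relative_risk(440 + d1)
        lo2, _ = tdp_relative_risk(440 + d2)
        assert 1 + lo12 == pytest.approx((1 + lo1) * (1 + lo2), rel=1e-9)
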