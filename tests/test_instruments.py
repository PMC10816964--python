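"""Instrument scoring rules, boundary behaviour and invariants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bamsa import (
    MissingDataError,
    ValidationError,
    calibrate_questionnaire_measurement,
    score_bamsa,
    score_berlin,
    score_ess,
    score_nosas,
    score_stop_bang,
)
from conftest import make_record


class TestBamsa:
    @pytest.mark.parametrize(
        "overrides, expected",
        [
            # all five risk factors present
            (dict(sex="male", bmi_visit=32, age_years=55, snoring_freq=4, apnea_freq=3), 5),
            # none present
            (dict(sex="female", bmi_visit=22, age_years=30, snoring_freq=1, apnea_freq=1), 0),
            # male + weekly snoring only (cohort-median anthropometrics)
            (dict(sex="male", bmi_visit=27.3, age_years=41.4, snoring_freq=3, apnea_freq=1), 2),
            # strict thresholds: BMI and age exactly at the boundary score 0
            (dict(sex="male", bmi_visit=30.0, age_years=50.0, snoring_freq=2, apnea_freq=2), 2),
        ],
    )
    def test_examples(self, overrides, expected):
        assert score_bamsa(make_record(**overrides)) == expected

    @given(
        bmi=st.floats(15, 45),
        age=st.floats(20, 70),
        male=st.booleans(),
        snoring=st.integers(1, 5),
        apnea=st.integers(1, 5),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_and_bounded(self, bmi, age, male, snoring, apnea):
        """Switching any single risk factor on never decreases the score."""
        r = make_record(
            bmi_visit=bmi, age_years=age, sex="male" if male else "female",
            snoring_freq=snoring, apnea_freq=apnea,
        )
        base = score_bamsa(r)
        assert 0 <= base <= 5
        for on in (
            dict(bmi_visit=35.0), dict(age_years=60.0), dict(sex="male"),
            dict(snoring_freq=5), dict(apnea_freq=5),
        ):
            merged = dict(
                bmi_visit=bmi, age_years=age, sex="male" if male else "female",
                snoring_freq=snoring, apnea_freq=apnea,
            )
            merged.update(on)
            assert score_bamsa(make_record(**merged)) >= base


class TestStopBang:
    def _negative(self):
        return dict(
            sex="female", bmi_visit=22, age_years=30, neck_cm_visit=36,
            snoring_freq=1, apnea_freq=1, tiredness_freq=1, hypertension=False,
        )

    def test_all_negative_is_zero(self):
        assert score_stop_bang(make_record(**self._negative())) == 0

    def test_all_positive_is_eight(self):
        r = make_record(
            sex="male", bmi_visit=40, age_years=60, neck_cm_visit=46,
            snoring_freq=5, apnea_freq=5, tiredness_freq=5, hypertension=True,
        )
        for variant in ("original", "new"):
            assert score_stop_bang(r, variant) == 8

    def test_neck_variants_differ_only_in_neck_item(self):
        # male with 42 cm neck: above the original 40 cm threshold, below
        # the updated male-specific 43 cm threshold
        r = make_record(**{**self._negative(), "sex": "male", "neck_cm_visit": 42})
        assert score_stop_bang(r, "original") - score_stop_bang(r, "new") == 1

    @given(
        neck=st.floats(34, 48),
        bmi=st.floats(18, 45),
        age=st.floats(20, 70),
        male=st.booleans(),
        snoring=st.integers(1, 5),
        tired=st.integers(1, 5),
        apnea=st.integers(1, 5),
        htn=st.booleans(),
    )
    @settings(max_examples=100, derandomize=True)
    def test_variants_agree_when_neck_agrees(
        self, neck, bmi, age, male, snoring, tired, apnea, htn
    ):
        r = make_record(
            neck_cm_visit=neck, bmi_visit=bmi, age_years=age,
            sex="male" if male else "female", snoring_freq=snoring,
            tiredness_freq=tired, apnea_freq=apnea, hypertension=htn,
        )
        orig, new = score_stop_bang(r, "original"), score_stop_bang(r, "new")
        neck_orig = neck > 40
        neck_new = neck > (43 if male else 41)
        assert orig - new == int(neck_orig) - int(neck_new)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValidationError):
            score_stop_bang(make_record(), "older")

    def test_missing_tiredness_raises(self):
        with pytest.raises(MissingDataError):
            score_stop_bang(make_record(tiredness_freq=None))


class TestNosas:
    @pytest.mark.parametrize(
        "overrides, expected",
        [
            (dict(neck_cm_visit=45, bmi_visit=31, snoring_freq=5, age_years=60, sex="male"), 17),
            (dict(neck_cm_visit=38, bmi_visit=24, snoring_freq=1, age_years=30, sex="female"), 0),
            # 4 (neck) + 3 (BMI 25-30) + 2 (snorer) + 0 (age 50) + 2 (male)
            (dict(neck_cm_visit=41, bmi_visit=27, snoring_freq=3, age_years=50, sex="male"), 11),
        ],
    )
    def test_examples(self, overrides, expected):
        assert score_nosas(make_record(**overrides)) == expected

    def test_bmi_contribution_has_exactly_two_steps(self):
        def at(bmi):
            return score_nosas(make_record(bmi_visit=bmi, neck_cm_visit=38,
                                           snoring_freq=1, age_years=30, sex="female"))
        values = [at(b) for b in (20, 24.9, 25.0, 29.9, 30.0, 40)]
        assert values == [0, 0, 3, 3, 5, 5]

    @given(
        neck=st.floats(30, 55), bmi=st.floats(16, 48),
        snoring=st.integers(1, 5), age=st.floats(20, 80), male=st.booleans(),
    )
    @settings(max_examples=100, derandomize=True)
    def test_bounded(self, neck, bmi, snoring, age, male):
        r = make_record(neck_cm_visit=neck, bmi_visit=bmi, snoring_freq=snoring,
                        age_years=age, sex="male" if male else "female")
        assert 0 <= score_nosas(r) <= 17


class TestBerlin:
    def test_no_positive_categories_low_risk(self):
        r = make_record(berlin_cat1_positive_items=0, berlin_cat2_positive_items=0,
                        hypertension=False, bmi_visit=24)
        assert not score_berlin(r).high_risk

    def test_obesity_counts_as_category_three(self):
        # category 1 (3 positive items) + category 3 (BMI > 30) -> high risk
        r = make_record(berlin_cat1_positive_items=3, berlin_cat2_positive_items=0,
                        hypertension=False, bmi_visit=31)
        res = score_berlin(r)
        assert res.cat1_positive and res.cat3_positive and res.high_risk

    def test_single_positive_category_is_low_risk(self):
        r = make_record(berlin_cat1_positive_items=0, berlin_cat2_positive_items=0,
                        hypertension=False, bmi_visit=31)
        res = score_berlin(r)
        assert res.cat3_positive and not res.high_risk


class TestEss:
    def test_extremes(self):
        assert score_ess(make_record(ess_items=[0] * 8)) == 0
        assert score_ess(make_record(ess_items=[3] * 8)) == 24

    def test_cohort_median_example(self):
        assert score_ess(make_record(ess_items=(1, 1, 2, 0, 1, 2, 1, 1))) == 9

    def test_out_of_range_item_rejected(self):
        with pytest.raises(ValidationError):
            make_record(ess_items=(4, 0, 0, 0, 0, 0, 0, 0))

    @given(items=st.lists(st.integers(0, 3), min_size=8, max_size=8))
    @settings(max_examples=100, derandomize=True)
    def test_sum_and_permutation_invariance(self, items):
        total = score_ess(make_record(ess_items=items))
        assert total == sum(items)
        assert total == score_ess(make_record(ess_items=list(reversed(items))))


class TestCalibration:
    def test_printed_lines(self):
        assert calibrate_questionnaire_measurement(30.0, "bmi") == pytest.approx(29.75)
        assert calibrate_questionnaire_measurement(40.0, "neck") == pytest.approx(40.39)

    def test_bmi_fixed_point(self):
        x = 2.36 / (1 - 0.913)
        assert calibrate_questionnaire_measurement(x, "bmi") == pytest.approx(x)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            calibrate_questionnaire_measurement(0.0, "bmi")
        with pytest.raises(ValidationError):
            calibrate_questionnaire_measurement(40.0, "waist")
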