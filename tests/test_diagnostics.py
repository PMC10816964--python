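"""2x2 accuracy statistics, ROC/AUC and paired AUC comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from bamsa import (
    ConfusionTable,
    SingleClassError,
    ValidationError,
    accuracy_metrics,
    auc,
    bootstrap_compare,
    delong_compare,
    roc_curve,
)
from bamsa.rounding import round_half_away


class TestAccuracyMetrics:
    def test_published_moderate_osa_row(self):
        """The flagship cut-off: 24/28/4/104 against moderate-severe OSA."""
        s = accuracy_metrics(ConfusionTable(tp=24, fp=28, fn=4, tn=104))
        assert round_half_away(100 * s.sens.value, 1) == 85.7
        assert round_half_away(100 * s.spec.value, 1) == 78.8
        assert round_half_away(100 * s.ppv.value, 1) == 46.2
        assert round_half_away(100 * s.npv.value, 1) == 96.3
        assert round_half_away(s.lr_pos, 2) == 4.04
        assert round_half_away(s.lr_neg, 3) == 0.181
        assert round_half_away(s.odds_ratio, 1) == 22.3
        assert round_half_away(s.roc_area_dichotomous, 3) == 0.823

    def test_perfect_sensitivity_has_undefined_odds_ratio(self):
        s = accuracy_metrics(ConfusionTable(tp=28, fp=70, fn=0, tn=62))
        assert s.sens.value == 1.0
        assert s.lr_neg == 0.0
        assert s.odds_ratio is None
        assert round_half_away(s.lr_pos, 2) == 1.89
        assert round_half_away(s.roc_area_dichotomous, 3) == 0.735

    def test_zero_positive_calls_leaves_ppv_undefined(self):
        s = accuracy_metrics(ConfusionTable(tp=0, fp=0, fn=5, tn=7))
        assert s.ppv is None
        assert s.npv is not None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionTable(tp=-1, fp=0, fn=1, tn=1)

    def test_exact_interval_upper_bound_is_one_at_full_sensitivity(self):
        s = accuracy_metrics(ConfusionTable(tp=28, fp=70, fn=0, tn=62))
        assert s.sens.ci_high == 1.0
        assert s.sens.ci_low < 1.0

    def test_intervals_bracket_the_estimate(self):
        s = accuracy_metrics(ConfusionTable(tp=24, fp=28, fn=4, tn=104))
        for p in (s.sens, s.spec, s.ppv, s.npv):
            assert p.ci_low <= p.value <= p.ci_high

    @given(
        tp=st.integers(1, 200), fp=st.integers(1, 200),
        fn=st.integers(1, 200), tn=st.integers(1, 200),
    )
    @settings(max_examples=200, derandomize=True)
    def test_odds_ratio_identities(self, tp, fp, fn, tn):
        """LR+/LR- equals the cross-product OR; dichotomous ROC is (sens+spec)/2."""
        s = accuracy_metrics(ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn))
        cross = (tp * tn) / (fp * fn)
        assert s.lr_pos / s.lr_neg == pytest.approx(cross, rel=1e-12)
        assert s.odds_ratio == pytest.approx(cross, rel=1e-12)
        assert s.roc_area_dichotomous == pytest.approx(
            (s.sens.value + s.spec.value) / 2, abs=1e-15
        )


class TestRocCurve:
    def test_perfect_separation_contains_ideal_point(self):
        curve = roc_curve([1, 2, 3], [0, 0, 1])
        assert (0.0, 1.0) in curve.points
        assert curve.points[0] == (0.0, 0.0)
        assert curve.points[-1] == (1.0, 1.0)

    def test_constant_scores_jump_straight_to_one_one(self):
        curve = roc_curve([2, 2, 2, 2], [0, 1, 0, 1])
        assert curve.points == [(0.0, 0.0), (1.0, 1.0)]
        assert auc([2, 2, 2, 2], [0, 1, 0, 1]) == 0.5

    def test_binary_scores_single_interior_point(self):
        scores = [1, 0, 1, 0, 0, 1]
        outcome = [1, 0, 1, 1, 0, 0]
        curve = roc_curve(scores, outcome)
        t = ConfusionTable.from_predictions(np.array(scores) >= 1, outcome)
        s = accuracy_metrics(t)
        assert len(curve.points) == 3
        assert curve.points[1] == pytest.approx((1 - s.spec.value, s.sens.value))

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            roc_curve([1, 2, 3], [1, 1, 1])

    @given(st.data())
    @settings(max_examples=100, derandomize=True)
    def test_monotone_and_anchored(self, data):
        n = data.draw(st.integers(4, 30))
        scores = data.draw(st.lists(st.integers(0, 6), min_size=n, max_size=n))
        outcome = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda o: any(o) and not all(o)
            )
        )
        curve = roc_curve(scores, outcome)
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)
        assert curve.points[0] == (0.0, 0.0) and curve.points[-1] == (1.0, 1.0)


class TestAuc:
    def test_extremes(self):
        assert auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    @given(st.data())
    @settings(max_examples=150, derandomize=True)
    def test_matches_reference_implementation(self, data):
        """Midrank AUC equals sklearn's and the trapezoidal curve area."""
        n = data.draw(st.integers(4, 40))
        scores = data.draw(st.lists(st.integers(-5, 5), min_size=n, max_size=n))
        outcome = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda o: any(o) and not all(o)
            )
        )
        ours = auc(scores, outcome)
        assert ours == pytest.approx(roc_auc_score(outcome, scores), abs=1e-12)
        curve = roc_curve(scores, outcome)
        assert ours == pytest.approx(np.trapezoid(curve.tpr, curve.fpr), abs=1e-12)

    @given(st.data())
    @settings(max_examples=100, derandomize=True)
    def test_invariant_under_increasing_transform(self, data):
        n = data.draw(st.integers(4, 30))
        scores = np.array(
            data.draw(st.lists(st.integers(-4, 4), min_size=n, max_size=n)), float
        )
        outcome = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda o: any(o) and not all(o)
            )
        )
        base = auc(scores, outcome)
        assert auc(np.exp(scores), outcome) == pytest.approx(base, abs=1e-12)
        assert auc(3.0 * scores + 7.0, outcome) == pytest.approx(base, abs=1e-12)


FIXTURE_OUTCOME = np.array([1] * 7 + [0] * 13, dtype=bool)
FIXTURE_A = np.array(
    [8, 7, 6, 7, 5, 6, 4, 5, 4, 3, 2, 6, 3, 2, 1, 4, 3, 2, 5, 1], float
)
FIXTURE_B = np.array(
    [6, 5, 7, 4, 5, 3, 4, 5, 6, 2, 4, 3, 5, 2, 3, 4, 1, 2, 6, 2], float
)


class TestDelong:
    def test_identical_classifiers(self):
        res = delong_compare(FIXTURE_A, FIXTURE_A, FIXTURE_OUTCOME)
        assert res.z == 0.0 and res.p_value == 1.0

    def test_symmetry(self):
        ab = delong_compare(FIXTURE_A, FIXTURE_B, FIXTURE_OUTCOME)
        ba = delong_compare(FIXTURE_B, FIXTURE_A, FIXTURE_OUTCOME)
        assert ab.p_value == pytest.approx(ba.p_value, abs=1e-15)
        assert ab.z == pytest.approx(-ba.z, abs=1e-15)

    def test_auc_components_match_direct_auc(self):
        res = delong_compare(FIXTURE_A, FIXTURE_B, FIXTURE_OUTCOME)
        assert res.auc_a == pytest.approx(auc(FIXTURE_A, FIXTURE_OUTCOME), abs=1e-12)
        assert res.auc_b == pytest.approx(auc(FIXTURE_B, FIXTURE_OUTCOME), abs=1e-12)

    def test_agrees_with_stratified_bootstrap(self):
        """The asymptotic p-value is consistent with a 10^4-resample
        stratified bootstrap of the paired AUC difference."""
        d = delong_compare(FIXTURE_A, FIXTURE_B, FIXTURE_OUTCOME)
        b = bootstrap_compare(
            FIXTURE_A, FIXTURE_B, FIXTURE_OUTCOME,
            n_boot=10_000, rng=np.random.default_rng(42),
        )
        assert d.p_value == pytest.approx(b.p_value, abs=0.05)
        assert d.z == pytest.approx(b.z, rel=0.25)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            delong_compare([1, 2], [2, 1], [1, 1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            delong_compare([1, 2, 3], [1, 2], [1, 0, 1])
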