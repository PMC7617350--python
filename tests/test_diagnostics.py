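"""Exact binomial statistics, ROC, paired intervals and stratified evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from widcfoc.diagnostics import (
    StratumSpec,
    clopper_pearson,
    evaluate_strata,
    paired_concordance,
    paired_difference_ci,
    roc_curve,
    sens_spec,
    stage_detection_table,
)
from widcfoc.scoring import EXCLUDED, NEGATIVE, POSITIVE, ScoreCall
from widcfoc.simulate import SubjectRecord


class TestClopperPearson:
    def test_zero_successes_lower_bound_is_zero(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0
        assert 0 < hi < 1

    def test_all_successes_upper_bound_is_one_and_lower_is_analytic(self):
        lo, hi = clopper_pearson(29, 29)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 29))  # (alpha/2)^(1/n)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson(0, 0)

    @settings(max_examples=60, deadline=None)
    @given(n=st.integers(1, 60), x=st.integers(0, 60))
    def test_bounds_bracket_point_and_are_monotone_in_x(self, n, x):
        x = min(x, n)
        lo, hi = clopper_pearson(x, n)
        assert 0 <= lo <= x / n <= hi <= 1
        if x < n:
            lo2, hi2 = clopper_pearson(x + 1, n)
            assert lo2 >= lo and hi2 >= hi


class TestSensSpec:
    def test_sixteen_of_twenty_high_risk_cases(self):
        preds = [POSITIVE] * 16 + [NEGATIVE] * 4 + [NEGATIVE] * 40 + [POSITIVE]
        truth = [True] * 20 + [False] * 41
        out = sens_spec(preds, truth)
        sens = out["sensitivity"]
        assert (sens.x, sens.n) == (16, 20)
        assert sens.display() == "80.0% (56.3%-94.3%)"
        spec = out["specificity"]
        assert (spec.x, spec.n) == (40, 41)
        assert spec.display() == "97.6% (87.1%-99.9%)"

    def test_perfect_classifier(self):
        out = sens_spec([True] * 5 + [False] * 7, [True] * 5 + [False] * 7)
        assert out["sensitivity"].point == 1.0
        assert out["specificity"].point == 1.0
        assert out["sensitivity"].ci_upper == 1.0

    def test_excluded_predictions_dropped_and_counted(self):
        preds = [POSITIVE, EXCLUDED, NEGATIVE, EXCLUDED]
        truth = [True, True, False, False]
        out = sens_spec(preds, truth)
        assert out["sensitivity"].n == 1
        assert out["specificity"].n == 1
        assert out["sensitivity"].n_excluded == 2

    def test_one_sided_input_returns_none_for_missing_side(self):
        out = sens_spec([True, False], [True, True])
        assert out["specificity"] is None
        assert out["sensitivity"].n == 2


class TestROC:
    def test_perfect_separation_auc_one(self):
        _, auc = roc_curve([0, 1, 2, 10, 11], [False, False, False, True, True])
        assert auc == 1.0

    def test_uninformative_scores_auc_near_half(self):
        rng = np.random.default_rng(7)
        n = 2000
        scores = rng.normal(size=n)
        labels = rng.random(n) < 0.5
        _, auc = roc_curve(scores, labels)
        n1, n0 = labels.sum(), (~labels).sum()
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(auc - 0.5) < 3 * se

    def test_auc_equals_pairwise_concordance_count(self):
        """Mann-Whitney normalization vs explicit pair enumeration, with ties."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(4, 25))
            scores = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            _, auc = roc_curve(scores, labels)
            cases = scores[labels]
            controls = scores[~labels]
            num = sum(
                1.0 if c > k else 0.5 if c == k else 0.0
                for c in cases
                for k in controls
            )
            assert auc == pytest.approx(num / (len(cases) * len(controls)))
            from sklearn.metrics import roc_auc_score

            assert auc == pytest.approx(roc_auc_score(labels, scores))

    def test_roc_curve_endpoints(self):
        df, _ = roc_curve([1, 2, 3, 4], [False, False, True, True])
        assert df.iloc[0][["fpr", "tpr"]].tolist() == [1.0, 1.0]
        assert df.iloc[-1][["fpr", "tpr"]].tolist() == [0.0, 0.0]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2], [True, True])


class TestPairedDifferenceCI:
    def test_all_zero_differences(self):
        ci = paired_difference_ci([0.0, 0.0, 0.0])
        assert (ci.lower, ci.upper) == (0.0, 0.0)

    def test_two_observations_hand_computed(self):
        # delta=0.5, SD=0.70711, t(0.975, 1)=12.7062 -> 0.5 +- 6.3531
        ci = paired_difference_ci([1.0, 0.0])
        assert ci.delta == pytest.approx(0.5)
        assert ci.sd == pytest.approx(0.7071068, abs=1e-6)
        assert ci.t_crit == pytest.approx(12.7062, abs=1e-3)
        assert ci.lower == pytest.approx(-5.853, abs=1e-3)
        assert ci.upper == pytest.approx(6.853, abs=1e-3)

    def test_width_scales_as_inverse_sqrt_n(self):
        from scipy import stats

        base = [1.0, -1.0, 2.0, -2.0]
        ci4 = paired_difference_ci(base)
        ci16 = paired_difference_ci(base * 4)  # same SD, N scaled 4x
        width_ratio = (ci4.upper - ci4.lower) / (ci16.upper - ci16.lower)
        t_ratio = stats.t.ppf(0.975, 3) / stats.t.ppf(0.975, 15)
        sd_ratio = ci4.sd / ci16.sd
        assert width_ratio == pytest.approx(2 * t_ratio * sd_ratio, rel=1e-9)

    def test_sd_as_se_switch_drops_sqrt_n(self):
        d = [1.0, 2.0, 3.0, 4.0]
        a = paired_difference_ci(d)
        b = paired_difference_ci(d, sd_is_se=True)
        assert (b.upper - b.lower) == pytest.approx(2 * (a.upper - a.lower))

    def test_single_difference_rejected(self):
        with pytest.raises(ValueError):
            paired_difference_ci([1.0])


class TestPairedConcordance:
    def test_identical_vectors_fully_concordant(self):
        vals = [0.1, 0.5, 0.9, 2.0, 3.0, 5.0]
        out = paired_concordance(vals, vals, split_at=1.0)
        assert out["r_above"] == pytest.approx(1.0)
        assert out["r_at_or_below"] == pytest.approx(1.0)

    def test_constant_vector_undefined_correlation(self):
        out = paired_concordance([2.0, 2.0, 2.0], [1.0, 2.0, 3.0], split_at=0.0)
        assert out["r_above"] is None

    def test_tiny_stratum_undefined(self):
        out = paired_concordance([5.0, 6.0], [5.0, 6.0], split_at=1.0)
        assert out["r_above"] is None
        assert out["n_above"] == 2

    def test_discordant_call_count(self):
        day = [0.5, 2.0, 3.0]
        night = [1.5, 0.5, 3.5]
        out = paired_concordance(day, night, call_threshold=1.0)
        assert out["n_discordant_calls"] == 2


def _subject(sid, case, grade="3", stage="III", days=None, brca="unknown"):
    import datetime

    s0 = datetime.date(2020, 1, 1)
    return SubjectRecord(
        subject_id=sid,
        group="cancer" if case else "control_healthy",
        grade=grade if case else "unknown",
        stage=stage if case else "unknown",
        brca_status=brca,
        sample_date=s0,
        diagnosis_date=(
            s0 + datetime.timedelta(days=days) if case and days is not None else None
        ),
        tumor_fraction_truth=0.01 if case else 0.0,
    )


def _score(sid, wid, ca=NEGATIVE):
    return ScoreCall(sid, {"R1": 5.0 if wid else 0.0}, wid, ca)


class TestEvaluateStrata:
    def _cohort(self):
        subjects = [
            _subject("c1", True, grade="3", days=100),
            _subject("c2", True, grade="3", days=400),
            _subject("c3", True, grade="1", days=50),
            _subject("n1", False),
            _subject("n2", False),
        ]
        scores = {
            "c1": _score("c1", True, POSITIVE),
            "c2": _score("c2", False, NEGATIVE),
            "c3": _score("c3", False, NEGATIVE),
            "n1": _score("n1", False, NEGATIVE),
            "n2": _score("n2", True, NEGATIVE),
        }
        return subjects, scores

    def test_high_risk_and_time_strata_counts(self):
        subjects, scores = self._cohort()
        strata = [
            StratumSpec("all"),
            StratumSpec("high_risk", high_risk=True),
            StratumSpec("lt1yr", max_days_to_diagnosis=365),
        ]
        ests = {
            (e.stratum, e.marker, e.metric): e
            for e in evaluate_strata(subjects, scores, None, strata)
        }
        assert ests[("all", "wid_cfoc", "sensitivity")].n == 3
        assert ests[("high_risk", "wid_cfoc", "sensitivity")].n == 2
        assert ests[("lt1yr", "wid_cfoc", "sensitivity")].n == 2
        # controls pass case-only filters -> specificity estimable everywhere
        assert ests[("high_risk", "wid_cfoc", "specificity")].n == 2

    def test_complementary_strata_counts_sum_to_total(self):
        subjects, scores = self._cohort()
        strata = [
            StratumSpec("all"),
            StratumSpec("hr", high_risk=True),
            StratumSpec("lr", high_risk=False),
        ]
        ests = {
            (e.stratum, e.metric): e
            for e in evaluate_strata(subjects, scores, None, strata,
                                     markers=("wid_cfoc",))
        }
        assert (
            ests[("hr", "sensitivity")].n + ests[("lr", "sensitivity")].n
            == ests[("all", "sensitivity")].n
        )
        assert (
            ests[("hr", "sensitivity")].x + ests[("lr", "sensitivity")].x
            == ests[("all", "sensitivity")].x
        )

    def test_empty_stratum_yields_no_rows_without_error(self):
        subjects, scores = self._cohort()
        out = evaluate_strata(
            subjects, scores, None, [StratumSpec("stage_iv", stage="IV")]
        )
        # only controls admit -> specificity rows exist, sensitivity absent
        assert all(e.metric == "specificity" for e in out)

    def test_stage_detection_table(self):
        subjects, scores = self._cohort()
        table = stage_detection_table(subjects, scores)
        row = table.set_index("stage").loc["III"]
        assert row["total"] == 3
        assert row["detected"] == 1
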