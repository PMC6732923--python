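"""Outcome derivations and the statistical battery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import special

from perflung.stats import (
    bonferroni_alpha,
    classify_rali,
    fractional_change,
    mann_whitney_u,
    median_split,
    roc_analysis,
    run_full_analysis,
    student_t_test,
)
from perflung.synthetic import cohort_tables, simulate_cohort


class TestFractionalChange:
    def test_nadir_decline(self):
        c = fractional_change({3: 1.5, 12: 1.8}, baseline=2.0)
        assert c.change_pct == pytest.approx(-25.0)

    def test_no_change(self):
        c = fractional_change({3: 2.0, 6: 2.0}, baseline=2.0)
        assert c.change_pct == 0.0

    def test_summary_rules(self):
        series = {3: 1.8, 12: 1.6, 24: 1.9}
        assert fractional_change(series, 2.0, "nadir").change_pct == pytest.approx(-20.0)
        assert fractional_change(series, 2.0, "last").change_pct == pytest.approx(-5.0)
        assert fractional_change(
            series, 2.0, "at_month", at_month=3
        ).change_pct == pytest.approx(-10.0)

    def test_no_followups_raises(self):
        with pytest.raises(ValueError, match="follow-up"):
            fractional_change({}, baseline=2.0)


class TestMedianSplit:
    @staticmethod
    def _changes(values):
        return [
            fractional_change({12: 2.0 * (1 + v / 100)}, 2.0, patient_id=f"P{i}")
            for i, v in enumerate(values)
        ]

    def test_odd_cohort(self):
        labels = median_split(self._changes([-30, -10, 0]))
        assert labels["P0"] == "deteriorating"
        assert labels["P1"] == "stable" and labels["P2"] == "stable"

    def test_41_distinct_values_split_20_21(self, rng):
        vals = rng.permutation(np.linspace(-40, 10, 41))
        labels = median_split(self._changes(vals))
        assert (labels == "deteriorating").sum() == 20
        assert (labels == "stable").sum() == 21

    def test_median_tie_goes_to_stable_by_enumeration(self):
        values = [-10.0, -5.0, -5.0, 0.0]
        labels = median_split(self._changes(values))
        med = np.median(values)
        for i, v in enumerate(values):  # exhaustive check of the rule
            expected = "deteriorating" if v < med else "stable"
            assert labels[f"P{i}"] == expected
        assert (labels == "stable").sum() == 3

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            median_split(self._changes([-5.0, -5.0, -5.0]))


class TestClassifyRali:
    def test_low_grades_everywhere(self):
        assert classify_rali({1: 1, 3: 1, 6: 0}, "early") is False
        assert classify_rali({1: 1, 3: 1, 6: 0}, "any") is False

    def test_early_grade2_is_event_in_both_windows(self):
        assert classify_rali({3: 2}, "early") is True
        assert classify_rali({3: 2}, "any") is True

    def test_late_event_missing_in_early_window(self):
        assert classify_rali({12: 3}, "early") is None
        assert classify_rali({12: 3}, "any") is True

    def test_grade_validation(self):
        with pytest.raises(ValueError):
            classify_rali({3: 7})


class TestStudentT:
    def test_identical_groups(self):
        res = student_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)
        assert res.difference == 0.0

    def test_clear_separation(self):
        res = student_t_test([1.0, 1.01, 1.02], [11.0, 11.01, 11.02])
        assert res.p_value < 1e-6
        assert res.difference == pytest.approx(10.0)

    def test_matches_textbook_formula(self, rng):
        """Pooled-variance t and its p-value recomputed from the incomplete
        beta function agree to 1e-10."""
        a = rng.normal(10, 2, size=7)
        b = rng.normal(12, 3, size=9)
        res = student_t_test(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
        p = special.betainc(df / 2, 0.5, df / (df + t * t))
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="pooled variance"):
            student_t_test([2.0, 2.0], [2.0, 2.0])


class TestMannWhitney:
    def test_exact_small_sample(self):
        res = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2.0 / 6.0)

    def test_single_tied_values(self):
        res = mann_whitney_u([5.0], [5.0])
        assert res.statistic == 0.5
        assert res.p_value == 1.0

    def test_exact_vs_asymptotic_at_n12(self, rng):
        """The continuity-corrected normal approximation agrees with
        exhaustive enumeration within 0.02 at a pooled size of 12."""
        for _ in range(10):
            a = rng.normal(0, 1, size=6)
            b = rng.normal(0.5, 1, size=6)
            exact = mann_whitney_u(a, b).p_value
            approx = mann_whitney_u(a, b, exact_max_n=0).p_value
            assert abs(exact - approx) <= 0.02

    def test_asymptotic_matches_scipy(self, rng):
        from scipy import stats as sps

        a = rng.normal(0, 1, size=20)
        b = rng.normal(0.7, 1, size=15)
        ours = mann_whitney_u(a, b).p_value
        ref = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
        assert ours == pytest.approx(ref, abs=1e-10)


class TestBonferroni:
    def test_values(self):
        assert bonferroni_alpha(0.05, 8) == pytest.approx(0.00625)
        assert bonferroni_alpha(0.05, 1) == 0.05
        assert bonferroni_alpha(0.01, 4) == pytest.approx(0.0025)

    def test_validation(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(1.5, 8)
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.sensitivity_pct == 100.0 and res.specificity_pct == 100.0

    def test_null_metric_near_half(self, rng):
        x = rng.normal(size=600)
        y = rng.random(600) < 0.5
        assert abs(roc_analysis(x, y).auc - 0.5) < 0.08

    def test_six_point_toy_set_by_enumeration(self):
        pts = [(1, 0), (2, 0), (3, 1), (2.5, 1), (1.5, 0), (4, 1)]
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts], bool)
        res = roc_analysis(x, y)
        pos, neg = x[y], x[~y]
        brute_auc = sum(
            1.0 if p > n else (0.5 if p == n else 0.0)
            for p, n in itertools.product(pos, neg)
        ) / (len(pos) * len(neg))
        assert res.auc == pytest.approx(brute_auc)
        # brute-force Youden over all observed cutoffs, ties to lower cutoff
        best = None
        for c in sorted(np.unique(x)):
            sens = (pos >= c).mean()
            spec = (neg < c).mean()
            j = sens + spec - 1
            if best is None or j > best[0] + 1e-12:
                best = (j, c, sens, spec)
        assert res.cutoff == pytest.approx(best[1])
        assert res.sensitivity_pct == pytest.approx(100 * best[2])
        assert res.specificity_pct == pytest.approx(100 * best[3])

    def test_auc_equals_u_statistic(self, rng):
        """Cross-operation consistency: AUC == U/(n1 n0) exactly, ties
        included."""
        for _ in range(10):
            x = np.round(rng.normal(size=30), 1)
            y = rng.random(30) < 0.4
            if y.all() or not y.any():
                continue
            res = roc_analysis(x, y)
            n1, n0 = int(y.sum()), int((~y).sum())
            u_event = mann_whitney_u(x[y], x[~y]).statistic
            assert res.auc == pytest.approx(u_event / (n1 * n0))

    def test_label_inversion_flips_auc(self, rng):
        x = rng.normal(size=40)
        y = rng.random(40) < 0.5
        if not (y.any() and (~y).any()):
            y[0], y[1] = True, False
        a1 = roc_analysis(x, y).auc
        a2 = roc_analysis(x, ~y).auc
        assert a1 + a2 == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            roc_analysis([1, 2, 3], [1, 1, 1])

    def test_matches_sklearn_auc(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        x = rng.normal(size=50)
        y = rng.random(50) < 0.4
        if not (y.any() and (~y).any()):
            y[0], y[1] = True, False
        assert roc_analysis(x, y).auc == pytest.approx(
            sklearn_metrics.roc_auc_score(y, x)
        )


@pytest.fixture(scope="module")
def small_cohort():
    records, _ = simulate_cohort(41, seed=3)
    return cohort_tables(records)


class TestFullAnalysis:
    def test_eight_rows_per_table(self, small_cohort):
        metrics, visits = small_cohort
        report = run_full_analysis(metrics, visits)
        for table in (
            report.fev1_anatomic,
            report.fev1_perfused,
            report.rali_perfused,
            report.rali_anatomic,
        ):
            assert len(table) == 8  # the Bonferroni divisor
        assert report.bonferroni_threshold == pytest.approx(0.00625)

    def test_significance_flags_consistent(self, small_cohort):
        metrics, visits = small_cohort
        report = run_full_analysis(metrics, visits)
        thr = report.bonferroni_threshold
        for table in (report.fev1_anatomic, report.fev1_perfused):
            flagged = table["significant"]
            assert (table.loc[flagged, "p_value"] < thr).all()
            assert (table.loc[~flagged, "p_value"] >= thr).all()

    def test_median_split_sizes(self, small_cohort):
        metrics, visits = small_cohort
        report = run_full_analysis(metrics, visits)
        counts = report.labels["fev1_group"].value_counts()
        assert counts["stable"] == 21 and counts["deteriorating"] == 20

    def test_no_rali_events_not_estimable(self, small_cohort):
        metrics, visits = small_cohort
        visits = visits.copy()
        visits["ctcae_grade"] = 0  # force zero events
        report = run_full_analysis(metrics, visits)
        assert (report.rali_perfused["note"] == "not estimable (no events)").all()
        assert report.rali_perfused["p_value"].isna().all()

    def test_missing_columns_listed(self, small_cohort):
        metrics, visits = small_cohort
        broken = metrics.drop(columns=["aV10", "pMLD_cGy"])
        with pytest.raises(ValueError) as err:
            run_full_analysis(broken, visits)
        assert "aV10" in str(err.value) and "pMLD_cGy" in str(err.value)

    def test_generating_metric_has_top_auc_in_expectation(self, cohort200, rng):
        """Averaged over repeated outcome draws, the V10 row (the
        generating metric) attains the largest mean AUC among the
        anatomic thresholds."""
        from perflung.synthetic import OutcomeModel, simulate_outcomes

        _, metrics, _ = cohort200
        cols = metrics.drop(columns=["patient_id"]).select_dtypes("number")
        model = OutcomeModel()
        suffixes = ["aV5", "aV10", "aV13", "aV20", "aV30", "aV40", "aV50", "aMLD_cGy"]
        sums = dict.fromkeys(suffixes, 0.0)
        reps = 40
        for _ in range(reps):
            recs = simulate_outcomes(cols, model, rng)
            y = np.array([r.true_deterioration for r in recs])
            for s in suffixes:
                sums[s] += roc_analysis(cols[s].to_numpy(), y).auc
        means = {s: v / reps for s, v in sums.items()}
        for s in suffixes:
            assert means["aV10"] >= means[s] - 0.01
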