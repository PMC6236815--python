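"""Truth tables, diagnostic metrics and the random-flag baseline."""

import numpy as np
import pytest

from artqa.assessment import (
    BaselineModel,
    TruthTable,
    assess_categories,
    diagnostic_metrics,
    random_flag_sensitivity,
    truth_table,
)
from artqa.core import CoursePlan, CourseRecord, FractionRecord
from artqa.criteria import CATEGORIES, ViolationReport

# printed clinical truth-table rows (counts of 106 assessed fractions)
TABLE3 = {
    "all_major": (18, 51, 8, 29),
    "all_major_excluding_ptv": (0, 18, 26, 62),
    "oar": (0, 10, 25, 70),
    "target_with_ptv": (18, 46, 8, 34),
    "target_without_ptv": (0, 8, 26, 72),
}


def states_from_counts(tp, fn, fp, tn):
    flags = [True] * tp + [False] * fn + [True] * fp + [False] * tn
    viols = [True] * (tp + fn) + [False] * (fp + tn)
    return flags, viols


class TestTruthTable:
    def test_all_positive(self):
        tt = truth_table([True] * 10, [True] * 10)
        assert (tt.tp, tt.fn, tt.fp, tt.tn) == (10, 0, 0, 0)

    def test_clinical_counts_round_trip(self):
        flags, viols = states_from_counts(*TABLE3["all_major"])
        tt = truth_table(flags, viols)
        assert (tt.tp, tt.fn, tt.fp, tt.tn) == TABLE3["all_major"]
        assert tt.total == 106

    def test_random_vectors_match_exhaustive_tally(self, rng):
        flags = (rng.random(50) < 0.5).tolist()
        viols = (rng.random(50) < 0.5).tolist()
        tt = truth_table(flags, viols)
        counts = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
        for f, v in zip(flags, viols):
            key = ("tp" if v else "fp") if f else ("fn" if v else "tn")
            counts[key] += 1
        assert (tt.tp, tt.fn, tt.fp, tt.tn) == tuple(counts.values())
        assert tt.total == 50

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            truth_table([True], [True, False])

    def test_percent_formatting(self):
        tt = TruthTable(*TABLE3["all_major_excluding_ptv"])
        assert tt.percent_of_total(tt.fn) == 17  # 18 of 106


class TestDiagnosticMetrics:
    def test_all_major_sensitivity(self):
        m = diagnostic_metrics(TruthTable(18, 51, 8, 29))
        assert m.sensitivity == pytest.approx(18 / 69)
        assert m.as_percent()["sensitivity"] == 26.1

    def test_target_with_ptv_sensitivity_upper_end(self):
        m = diagnostic_metrics(TruthTable(18, 46, 8, 34))
        assert m.sensitivity == pytest.approx(18 / 64)
        assert round(100 * m.sensitivity) == 28

    def test_degenerate_denominators_reported_absent(self):
        m = diagnostic_metrics(TruthTable(0, 0, 5, 5))
        assert m.sensitivity is None
        assert m.npv == 1.0
        assert m.specificity == 0.5

    def test_formula_definitions(self):
        m = diagnostic_metrics(TruthTable(3, 1, 2, 4))
        assert m.sensitivity == 3 / 4
        assert m.specificity == 4 / 6
        assert m.ppv == 3 / 5
        assert m.npv == 4 / 5
        assert m.accuracy == 7 / 10


def _cohort(flag_pattern, category_pattern):
    """One-course cohort with k assessed fractions and per-fraction reports."""
    k = len(flag_pattern)
    plan = CoursePlan(n_fractions=k)
    fractions = [
        FractionRecord(i + 1, assessed=True, contour_change=2.0 if f else 0.5,
                       flagged=f)
        for i, f in enumerate(flag_pattern)
    ]
    course = CourseRecord("p1", plan=plan, fractions=fractions)
    reports = [
        ViolationReport(i + 1, categories={c: bool(v) for c in CATEGORIES})
        for i, v in enumerate(category_pattern)
    ]
    return [course], reports


class TestAssessCategories:
    def test_matches_manual_composition(self, rng):
        flags = (rng.random(20) < 0.4).tolist()
        viols = (rng.random(20) < 0.3).tolist()
        courses, reports = _cohort(flags, viols)
        table = assess_categories(courses, reports)
        expected = truth_table(flags, viols)
        row = table.loc["all_major"]
        assert (row["tp"], row["fn"], row["fp"], row["tn"]) == (
            expected.tp, expected.fn, expected.fp, expected.tn,
        )

    def test_identical_rows_when_categories_agree(self, rng):
        flags = (rng.random(12) < 0.5).tolist()
        viols = (rng.random(12) < 0.5).tolist()
        courses, reports = _cohort(flags, viols)
        table = assess_categories(courses, reports)
        assert (table.loc["target_with_ptv", ["tp", "fn", "fp", "tn"]]
                == table.loc["target_without_ptv", ["tp", "fn", "fp", "tn"]]).all()

    def test_clean_cohort_is_all_true_negative(self):
        courses, reports = _cohort([False] * 8, [False] * 8)
        table = assess_categories(courses, reports)
        for cat in CATEGORIES:
            row = table.loc[cat]
            assert (row["tp"], row["fn"], row["fp"], row["tn"]) == (0, 0, 0, 8)

    def test_misaligned_reports_rejected(self):
        courses, reports = _cohort([True, False], [True, False])
        with pytest.raises(ValueError, match="reports"):
            assess_categories(courses, reports[:1])

    def test_fraction_weighting_changes_counts(self):
        courses, reports = _cohort([True, False], [True, True])
        table = assess_categories(courses, reports, weights=[2.0, 1.0])
        row = table.loc["all_major"]
        assert (row["tp"], row["fn"]) == (2.0, 1.0)


class TestRandomFlagBaseline:
    def test_certain_flagging_has_unit_sensitivity(self):
        res = random_flag_sensitivity(BaselineModel(p_flag=1.0, n_patients=500, seed=1))
        assert res.closed_form == 1.0
        assert res.mc_sensitivity == 1.0

    def test_unconditioned_sensitivity_equals_flag_rate(self):
        model = BaselineModel(p_flag=0.2, n_patients=200_000, seed=2,
                              condition_on_flagged=False)
        res = random_flag_sensitivity(model)
        assert res.closed_form == 0.2
        assert res.mc_sensitivity == pytest.approx(0.2, abs=3 * res.mc_standard_error)

    def test_conditioned_closed_form_and_monte_carlo_agree(self):
        model = BaselineModel(p_flag=0.2, p_viol=0.15, k=6, n_patients=100_000, seed=3)
        res = random_flag_sensitivity(model)
        assert res.closed_form == pytest.approx(0.2 / (1 - 0.8**6))
        assert abs(res.mc_sensitivity - res.closed_form) <= 3 * res.mc_standard_error

    def test_sensitivity_independent_of_violation_rate(self):
        # p_viol cancels under independence; estimates agree across a grid
        estimates = []
        for i, p_viol in enumerate((0.05, 0.15, 0.40)):
            res = random_flag_sensitivity(
                BaselineModel(p_viol=p_viol, n_patients=60_000, seed=10 + i)
            )
            estimates.append((res.mc_sensitivity, res.mc_standard_error))
        closed = BaselineModel().closed_form_sensitivity
        for mc, se in estimates:
            assert abs(mc - closed) <= 3 * se

    def test_conditioning_inflates_sensitivity_toward_flag_rate(self):
        # conditioned >= p_flag for all k, approaching p_flag as k grows
        prev = None
        for k in (1, 2, 6, 40):
            cf = BaselineModel(k=k).closed_form_sensitivity
            assert cf >= 0.2 - 1e-12
            if prev is not None:
                assert cf <= prev
            prev = cf
        assert BaselineModel(k=200).closed_form_sensitivity == pytest.approx(0.2, abs=1e-9)

    def test_zero_flag_rate_with_conditioning_rejected(self):
        with pytest.raises(ValueError, match="p_flag"):
            random_flag_sensitivity(BaselineModel(p_flag=0.0, n_patients=10))


class TestCohortParameterRecovery:
    def test_random_cohort_recovers_closed_form(self):
        """End-to-end: random cohort -> flag protocol -> pooled truth table."""
        from artqa.flagging import FlagProtocol, apply_flag
        from artqa.simulate import random_flag_cohort

        courses, violations = random_flag_cohort(
            n_patients=20_000, k=6, p_flag=0.20, p_viol=0.15, seed=11
        )
        flagged = [apply_flag(c, FlagProtocol(threshold=1.5)) for c in courses]
        # flagged-cohort inclusion: drop patients with no flagged fraction
        keep_flags, keep_viols = [], []
        i = 0
        for c in flagged:
            fx = c.assessed_fractions
            vs = violations[i:i + len(fx)]
            i += len(fx)
            if any(fr.flagged for fr in fx):
                keep_flags.extend(fr.flagged for fr in fx)
                keep_viols.extend(vs)
        tt = truth_table(keep_flags, keep_viols)
        sens = tt.tp / (tt.tp + tt.fn)
        closed = BaselineModel(k=6).closed_form_sensitivity
        se = np.sqrt(sens * (1 - sens) / (tt.tp + tt.fn))
        assert abs(sens - closed) <= 3 * se
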