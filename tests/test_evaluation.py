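from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from redlistrf import (
    ConfusionCounts,
    ValidationError,
    chi_square_two_classifications,
    chi_square_vs_random,
    confusion_from_summary,
    expected_correct,
    report_from_confusion,
)

counts = st.integers(min_value=0, max_value=500)


class TestReportFromConfusion:
    def test_butterfly_style_row(self):
        # published butterflies decline row: n=49, correct 87.76, α=0.333, β=0.054
        rep = report_from_confusion(ConfusionCounts(TP=35, FP=4, FN=2, TN=8))
        assert rep.correct_percent == pytest.approx(87.76, abs=0.005)
        assert rep.type1 == pytest.approx(0.333, abs=5e-4)
        assert rep.type2 == pytest.approx(0.054, abs=5e-4)

    def test_perfect_classifier(self):
        rep = report_from_confusion(ConfusionCounts(TP=30, FP=0, FN=0, TN=70))
        assert rep.correct_percent == 100.0
        assert rep.type1 == 0.0 and rep.type2 == 0.0

    def test_all_positive_predictor(self):
        rep = report_from_confusion(ConfusionCounts(TP=40, FP=60, FN=0, TN=0))
        assert rep.correct_percent == pytest.approx(100 * 0.4)
        assert rep.type1 == 1.0 and rep.type2 == 0.0

    def test_empty_class_errors(self):
        c = ConfusionCounts(TP=5, FP=0, FN=3, TN=0)
        with pytest.raises(ValidationError, match="Type I"):
            report_from_confusion(c)

    @given(tp=counts, fp=counts, fn=counts, tn=counts)
    @settings(max_examples=1000, deadline=None, derandomize=True)
    def test_accuracy_identity_exact(self, tp, fp, fn, tn):
        """(1-p)(1-α) + p(1-β) = C in exact rational arithmetic."""
        if tp + fn == 0 or fp + tn == 0:
            return
        n = tp + fp + fn + tn
        p = Fraction(tp + fn, n)
        alpha = Fraction(fp, fp + tn)
        beta = Fraction(fn, tp + fn)
        assert (1 - p) * (1 - alpha) + p * (1 - beta) == Fraction(tp + tn, n)
        rep = report_from_confusion(ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn))
        lhs = (1 - rep.prevalence) * (1 - rep.type1) + rep.prevalence * (1 - rep.type2)
        assert lhs == pytest.approx(rep.correct_percent / 100, abs=1e-10)


class TestConfusionFromSummary:
    @pytest.mark.parametrize(
        "n,prev,t1,t2,expected",
        [
            (175, 0.44, 0.224, 0.494, (39, 22, 38, 76)),
            (49, 0.76, 0.333, 0.054, (35, 4, 2, 8)),
            (100, 0.5, 0.0, 0.0, (50, 0, 0, 50)),
        ],
    )
    def test_reconstruction(self, n, prev, t1, t2, expected):
        c, consistent = confusion_from_summary(n, prev, t1, t2)
        assert (c.TP, c.FP, c.FN, c.TN) == expected
        assert consistent

    def test_reconstruction_unique_by_exhaustive_search(self):
        """Exhaustive integer search confirms the half-up reconstruction is
        the discrepancy-minimising confusion table."""
        n, prev, t1, t2 = 49, 0.76, 0.333, 0.054
        best, best_err = None, np.inf
        for pos in range(1, n):
            neg = n - pos
            for fp in range(neg + 1):
                for fn in range(pos + 1):
                    err = (
                        abs(pos / n - prev)
                        + abs(fp / neg - t1)
                        + abs(fn / pos - t2)
                    )
                    if err < best_err:
                        best, best_err = (pos - fn, fp, fn, neg - fp), err
        c, _ = confusion_from_summary(n, prev, t1, t2)
        assert (c.TP, c.FP, c.FN, c.TN) == best

    def test_roundtrip_with_full_precision_summary(self):
        c0 = ConfusionCounts(TP=31, FP=11, FN=9, TN=49)
        rep = report_from_confusion(c0)
        c1, consistent = confusion_from_summary(
            rep.n, rep.prevalence, rep.type1, rep.type2
        )
        assert c1 == c0 and consistent

    def test_inconsistent_summary_flagged(self):
        _, consistent = confusion_from_summary(100, 0.5, 0.3, 0.254)
        assert consistent  # exact rates survive rounding at n=100
        _, consistent = confusion_from_summary(7, 0.5, 0.21, 0.5)
        assert not consistent  # 0.21 of 3-4 negatives cannot be hit within 0.01


class TestExpectedCorrect:
    def test_birds_to_vertebrates_published_value(self):
        birds, _ = confusion_from_summary(77, 0.34, 0.176, 0.769)
        assert (birds.TP, birds.FP, birds.FN, birds.TN) == (6, 9, 20, 42)
        assert expected_correct(birds, 175, 0.44) == pytest.approx(56.27, abs=0.005)

    def test_perfect_indicator_always_100(self):
        c = ConfusionCounts(TP=20, FP=0, FN=0, TN=30)
        for p in (0.1, 0.44, 0.9):
            assert expected_correct(c, 200, p) == pytest.approx(100.0)

    def test_same_prevalence_recovers_own_correct(self):
        c = ConfusionCounts(TP=30, FP=10, FN=20, TN=40)
        rep = report_from_confusion(c)
        assert expected_correct(c, c.n, c.prevalence) == pytest.approx(
            rep.correct_percent
        )

    def test_linear_in_higher_prevalence(self):
        c = ConfusionCounts(TP=30, FP=10, FN=20, TN=40)
        n = 1000  # large n so the integer snap of p_h is negligible
        ps = np.array([0.2, 0.4, 0.6, 0.8])
        vals = np.array([expected_correct(c, n, p) for p in ps])
        slopes = np.diff(vals) / np.diff(ps)
        assert slopes == pytest.approx(
            [100 * (c.type1 - c.type2)] * 3, abs=0.5
        )


class TestChiSquare:
    def test_closed_form_value(self):
        res = chi_square_vs_random(ConfusionCounts(TP=35, FP=4, FN=2, TN=8))
        assert res.statistic == pytest.approx(49 * 272**2 / (37 * 12 * 39 * 10), abs=1e-9)
        assert res.statistic == pytest.approx(20.936, abs=5e-3)

    def test_independent_table_zero(self):
        res = chi_square_vs_random(ConfusionCounts(TP=25, FP=25, FN=25, TN=25))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_identical_row_distributions_zero(self):
        res = chi_square_vs_random(ConfusionCounts(TP=40, FP=20, FN=40, TN=20))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_zero_marginal_degenerate(self):
        res = chi_square_vs_random(ConfusionCounts(TP=50, FP=50, FN=0, TN=0))
        assert res.degenerate and res.p_value == 1.0

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 100:
            tp, fp, fn, tn = rng.integers(1, 200, size=4)
            table = np.array([[tp, fn], [fp, tn]])
            ours = chi_square_vs_random(ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn))
            ref = chi2_contingency(table, correction=False)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-6)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-6)
            checked += 1

    def test_yates_matches_scipy_corrected(self):
        ours = chi_square_vs_random(
            ConfusionCounts(TP=35, FP=4, FN=2, TN=8), yates=True
        )
        ref = chi2_contingency(np.array([[35, 2], [4, 8]]), correction=True)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-9)


class TestChiSquareTwoClassifications:
    def test_identical_classifications_zero(self):
        res = chi_square_two_classifications(80, 100, 80, 100)
        assert res.statistic == 0.0

    def test_closed_form(self):
        res = chi_square_two_classifications(90, 100, 60, 100)
        a, b, c, d = 90, 10, 60, 40
        n = 200
        expect = n * (a * d - b * c) ** 2 / (100 * 100 * (a + c) * (b + d))
        assert res.statistic == pytest.approx(expect, abs=1e-9)
        ref = chi2_contingency(np.array([[90, 10], [60, 40]]), correction=False)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)

    def test_extreme_association(self):
        res = chi_square_two_classifications(0, 100, 100, 100)
        assert res.p_value < 1e-10

    def test_out_of_range_errors(self):
        with pytest.raises(ValidationError):
            chi_square_two_classifications(101, 100, 50, 100)
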