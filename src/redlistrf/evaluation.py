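"""Classification metrics for rarity/decline forests.

The positive class throughout is *rare* / *declining*. Reported quantities:

* correct classification C = (TP + TN) / n, printed as a percentage,
* Type I error probability α = FP / (FP + TN) — a common or stable species
  classified as rare/declining (false-positive rate),
* Type II error probability β = FN / (TP + FN) — a rare or declining
  species classified as common/stable (false-negative rate),
* prevalence p = (TP + FN) / n,

linked by the exact identity C = (1 − p)(1 − α) + p(1 − β).

Two further operations support working with *published* summaries: integer
confusion counts can be reconstructed from a printed (n, prevalence, α, β)
row by half-up rounding, and an indicator group's error rates can be
re-projected onto a population with different prevalence p_h, giving the
prevalence-corrected expected correct classification
100·[(1 − p_h)(1 − α) + p_h(1 − β)].

Significance is assessed with the Pearson chi-square test (1 d.f., no
continuity correction unless requested); the statistic is computed in
closed form here, with scipy supplying only the chi-square tail probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import ValidationError


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ConfusionCounts:
    """2×2 confusion counts; positive class = rare / declining."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.n == 0:
            raise ValidationError("empty confusion table")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @property
    def prevalence(self) -> float:
        return (self.TP + self.FN) / self.n

    @property
    def type1(self) -> float:
        neg = self.FP + self.TN
        if neg == 0:
            raise ValidationError("Type I error undefined: no negative species")
        return self.FP / neg

    @property
    def type2(self) -> float:
        pos = self.TP + self.FN
        if pos == 0:
            raise ValidationError("Type II error undefined: no positive species")
        return self.FN / pos

    @property
    def correct(self) -> float:
        return (self.TP + self.TN) / self.n

    @classmethod
    def from_predictions(cls, truth, predicted) -> "ConfusionCounts":
        truth = np.asarray(truth).astype(int)
        predicted = np.asarray(predicted).astype(int)
        return cls(
            TP=int(((truth == 1) & (predicted == 1)).sum()),
            FP=int(((truth == 0) & (predicted == 1)).sum()),
            FN=int(((truth == 1) & (predicted == 0)).sum()),
            TN=int(((truth == 0) & (predicted == 0)).sum()),
        )


@dataclass(frozen=True)
class ClassificationReport:
    """Summary row: n, correct %, error probabilities, prevalence, p-value."""

    n: int
    correct_percent: float
    type1: float
    type2: float
    prevalence: float
    chi_square_p: float


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p_value: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def report_from_confusion(c: ConfusionCounts) -> ClassificationReport:
    """Full summary row from integer confusion counts."""
    chi = chi_square_vs_random(c)
    return ClassificationReport(
        n=c.n,
        correct_percent=100.0 * c.correct,
        type1=c.type1,
        type2=c.type2,
        prevalence=c.prevalence,
        chi_square_p=chi.p_value,
    )


def confusion_from_summary(
    n: int,
    prevalence: float,
    type1: float,
    type2: float,
) -> tuple[ConfusionCounts, bool]:
    """Reconstruct integer confusion counts behind a printed summary row.

    Positives = round(prevalence·n), FP = round(α·negatives),
    FN = round(β·positives), all half-up. Returns the counts plus a
    consistency flag that is False when the exact recomputed rates differ
    from the inputs by more than 0.01 (the summary was internally
    inconsistent at its printed precision).
    """
    if not (0.0 < prevalence < 1.0):
        raise ValidationError("prevalence must be in (0, 1)")
    if not (0.0 <= type1 <= 1.0 and 0.0 <= type2 <= 1.0):
        raise ValidationError("error probabilities must be in [0, 1]")
    positives = _round_half_up(prevalence * n)
    negatives = n - positives
    if positives == 0 or negatives == 0:
        raise ValidationError("reconstruction needs both classes present")
    FP = _round_half_up(type1 * negatives)
    FN = _round_half_up(type2 * positives)
    c = ConfusionCounts(TP=positives - FN, FP=FP, FN=FN, TN=negatives - FP)
    consistent = abs(c.type1 - type1) <= 0.01 and abs(c.type2 - type2) <= 0.01
    return c, consistent


def expected_correct(
    indicator: ConfusionCounts,
    higher_n: int,
    higher_prevalence: float,
) -> float:
    """Prevalence-corrected expected correct classification, in percent.

    Takes the indicator group's exact error-rate ratios α, β and asks what
    correct-classification percentage those rates would produce on a
    population of ``higher_n`` species with prevalence ``higher_prevalence``
    (snapped to an integer positive count):
    100·[(1 − p_h)(1 − α) + p_h(1 − β)].
    """
    if not (0.0 < higher_prevalence < 1.0):
        raise ValidationError("higher-group prevalence must be in (0, 1)")
    alpha = indicator.type1
    beta = indicator.type2
    p_h = _round_half_up(higher_prevalence * higher_n) / higher_n
    return 100.0 * ((1.0 - p_h) * (1.0 - alpha) + p_h * (1.0 - beta))


# ---------------------------------------------------------------------------
# Chi-square tests
# ---------------------------------------------------------------------------

def _pearson_chi2(table: np.ndarray, yates: bool = False) -> ChiSquareResult:
    """Pearson chi-square on a 2×2 table, closed form, 1 d.f."""
    a, b = float(table[0, 0]), float(table[0, 1])
    c, d = float(table[1, 0]), float(table[1, 1])
    N = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if N == 0 or 0 in margins:
        return ChiSquareResult(statistic=0.0, p_value=1.0, degenerate=True)
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - N / 2.0, 0.0)
    stat = N * diff**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return ChiSquareResult(statistic=stat, p_value=float(stats.chi2.sf(stat, df=1)))


def chi_square_vs_random(c: ConfusionCounts, yates: bool = False) -> ChiSquareResult:
    """Are positive species classified differently from negative ones?

    Pearson chi-square on the true-class × predicted-class table. A zero
    marginal (e.g. the classifier never predicts one class) yields p = 1
    with the degeneracy flag set.
    """
    table = np.array([[c.TP, c.FN], [c.FP, c.TN]], dtype=float)
    return _pearson_chi2(table, yates=yates)


def chi_square_two_classifications(
    a_correct: int,
    a_n: int,
    b_correct: int,
    b_n: int,
    yates: bool = False,
) -> ChiSquareResult:
    """Do two classifications differ in correct-classification fraction?

    Unpaired Pearson chi-square on the classification × (correct,
    incorrect) table.
    """
    for correct, n in ((a_correct, a_n), (b_correct, b_n)):
        if not (0 <= correct <= n):
            raise ValidationError("correct count outside [0, n]")
    table = np.array(
        [[a_correct, a_n - a_correct], [b_correct, b_n - b_correct]], dtype=float
    )
    return _pearson_chi2(table, yates=yates)
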