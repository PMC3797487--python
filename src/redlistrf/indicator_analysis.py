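"""Indicator-group transfer: train on a subgroup, classify its parent taxon.

A forest fitted to the decline labels of a well-studied *indicator* group
(birds, butterflies, vascular plants, ...) is applied to the enclosing
*higher taxonomic group*. Because the two populations differ in prevalence,
the indicator's own correct-classification percentage is first re-projected
onto the higher group's prevalence (the *expected* correct classification);
the transfer is informative exactly insofar as the *actual* percentage
departs from that expectation. The whole procedure — imputation of the
higher-group table included — is replicated (default 10×) to expose the
procedural randomness of the forests, and a Student-t 95 % confidence
interval over replicates accompanies the actual percentage. The top-10
permutation-importance lists of the indicator forest and of a forest grown
on the full higher group are intersected as a crude check that the two
models rely on the same attributes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import SpeciesTable, ValidationError
from .evaluation import (
    ClassificationReport,
    ConfusionCounts,
    expected_correct,
    report_from_confusion,
)
from .forest_engine import grow_forest, permutation_importance, predict
from .proximity_imputation import impute


def importance_overlap(top_a: list[str], top_b: list[str]) -> int:
    """Size of the intersection of two top-10 attribute lists."""
    if len(set(top_a)) != len(top_a) or len(set(top_b)) != len(top_b):
        raise ValidationError("duplicate names in an importance list")
    return len(set(top_a) & set(top_b))


def _stage_seed(master: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = zlib.crc32(f"{stage}:{index}".encode())
    return (int(master) * 1_000_003 + h) & 0x7FFFFFFF


@dataclass
class ReplicateRecord:
    """One imputation + forest replicate of the transfer experiment."""

    seed: int
    indicator_report: ClassificationReport
    transfer_report: ClassificationReport
    transfer_confusion: ConfusionCounts
    expected: float
    top10_indicator: list[str]
    top10_higher: list[str]
    overlap: int


@dataclass
class IndicatorResult:
    """Aggregated transfer performance of one indicator / higher-group pair."""

    indicator: str
    higher_group: str
    replicates: list[ReplicateRecord]
    actual_mean: float
    actual_ci: tuple[float, float]
    expected: float
    importance_overlap: int
    higher_n: int = 0
    higher_prevalence: float = 0.0

    def as_row(self) -> dict:
        """Summary row mirroring the published transfer-table layout."""
        rep = self.replicates[-1]
        return {
            "indicator": self.indicator,
            "indicator_prevalence": round(rep.indicator_report.prevalence, 2),
            "higher_group": self.higher_group,
            "n": self.higher_n,
            "prevalence": round(self.higher_prevalence, 2),
            "expected_correct_percent": round(self.expected, 2),
            "actual_correct_percent": round(self.actual_mean, 2),
            "chi_square_p": rep.transfer_report.chi_square_p,
            "type1": round(rep.transfer_report.type1, 3),
            "type2": round(rep.transfer_report.type2, 3),
        }


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    m = float(np.mean(values))
    if len(values) < 2 or float(np.std(values, ddof=1)) == 0.0:
        return (m, m)
    half = stats.t.ppf(0.5 + level / 2, df=len(values) - 1) * float(
        np.std(values, ddof=1)
    ) / np.sqrt(len(values))
    return (m - half, m + half)


def run_indicator(
    table: SpeciesTable,
    indicator: str,
    higher: str,
    axis: str = "decline",
    n_replicates: int = 10,
    seed: int = 0,
    n_trees: int = 10_000,
    imputation_trees: int = 1000,
    imputation_iterations: int = 10,
    include_indicator_rows: bool = True,
    ci_method: str = "t",
    compute_importance: bool = True,
) -> IndicatorResult:
    """Run the full indicator-transfer experiment.

    Per replicate: impute the higher-group table (label-aware), grow a
    forest on the indicator rows only, record its out-of-bag report,
    predict the higher-group rows, and compare the actual transfer correct
    percentage with the expectation derived from the indicator's OOB error
    rates at the higher group's prevalence.

    ``include_indicator_rows`` controls whether the indicator's own rows
    are part of the evaluated higher-group sample (the published design) or
    excluded; including them is optimistic for those rows since the forest
    has seen them in training.
    """
    ind_mask = table.group_mask(indicator)
    high_mask = table.group_mask(higher)
    if not ind_mask.any():
        raise ValidationError(f"indicator group {indicator!r} matches no species")
    if (ind_mask & ~high_mask).any():
        raise ValidationError(
            f"indicator {indicator!r} is not a subset of higher group {higher!r}"
        )
    higher_table = table.subset(high_mask)
    labels_all = higher_table.labels(axis)
    ind_in_high = ind_mask[high_mask]
    if len(np.unique(labels_all[ind_in_high])) < 2:
        raise ValidationError("indicator group has a single class")

    eval_mask = np.ones(len(labels_all), dtype=bool)
    if not include_indicator_rows:
        eval_mask = ~ind_in_high
        if not eval_mask.any():
            raise ValidationError("no evaluation rows outside the indicator group")

    records: list[ReplicateRecord] = []
    for r in range(n_replicates):
        imp_seed = _stage_seed(seed, "impute", r)
        forest_seed = _stage_seed(seed, "forest", r)
        completed = impute(
            higher_table,
            labels_all,
            n_trees=imputation_trees,
            n_iter=imputation_iterations,
            seed=imp_seed,
        )
        ind_table = completed.subset(ind_in_high)
        y_ind = labels_all[ind_in_high]
        model = grow_forest(ind_table, y_ind, n_trees=n_trees, seed=forest_seed)
        oob_conf = ConfusionCounts.from_predictions(y_ind, model.oob_prediction)
        ind_report = report_from_confusion(oob_conf)

        pred, _ = predict(model, completed)
        y_eval = labels_all[eval_mask]
        transfer_conf = ConfusionCounts.from_predictions(y_eval, pred[eval_mask])
        transfer_report = report_from_confusion(transfer_conf)
        p_h = float(np.mean(y_eval))
        exp = expected_correct(oob_conf, int(eval_mask.sum()), p_h)

        if compute_importance:
            top_ind = permutation_importance(
                model, ind_table, y_ind, seed=_stage_seed(seed, "imp-ind", r)
            ).top(10)
            higher_model = grow_forest(
                completed, labels_all, n_trees=n_trees,
                seed=_stage_seed(seed, "higher-forest", r),
            )
            top_high = permutation_importance(
                higher_model, completed, labels_all, seed=_stage_seed(seed, "imp-high", r)
            ).top(10)
            overlap = importance_overlap(top_ind, top_high)
        else:
            top_ind, top_high, overlap = [], [], 0

        records.append(
            ReplicateRecord(
                seed=forest_seed,
                indicator_report=ind_report,
                transfer_report=transfer_report,
                transfer_confusion=transfer_conf,
                expected=exp,
                top10_indicator=top_ind,
                top10_higher=top_high,
                overlap=overlap,
            )
        )

    actual = np.array([r.transfer_report.correct_percent for r in records])
    if ci_method == "t":
        ci = _t_ci(actual)
    elif ci_method == "normal":
        m, s = float(actual.mean()), float(actual.std(ddof=1)) if len(actual) > 1 else 0.0
        ci = (m - 1.96 * s, m + 1.96 * s)
    else:
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    mean_overlap = int(np.floor(np.mean([r.overlap for r in records]) + 0.5))
    return IndicatorResult(
        indicator=indicator,
        higher_group=higher,
        replicates=records,
        actual_mean=float(actual.mean()),
        actual_ci=ci,
        expected=float(np.mean([r.expected for r in records])),
        importance_overlap=mean_overlap,
        higher_n=int(eval_mask.sum()),
        higher_prevalence=float(np.mean(labels_all[eval_mask])),
    )
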