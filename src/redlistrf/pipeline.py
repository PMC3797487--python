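"""End-to-end orchestration: tier × axis classification runs and indicator
transfers, reproducing the standard report shapes of the analysis.

``run_full_analysis`` takes either file paths or a synthetic-data
configuration, then for every kingdom × axis × availability tier: selects
the tier's attribute columns (excluding past commonness for rarity),
filters uninformative/poorly observed attributes, imputes missing cells,
grows a forest, and emits a classification-report row plus the top-10
permutation importances. Indicator pairs are delegated to
:func:`redlistrf.indicator_analysis.run_indicator`.

``verify_reported_arithmetic`` re-derives, from printed summary statistics
of the four classical Dutch indicator groups, the correct-classification
percentages and the prevalence-corrected expected transfer value — a fast
self-check that the evaluation arithmetic matches the published numbers.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .attribute_engineering import filter_attributes
from .data_model import SpeciesTable, read_species_table, select_tier
from .evaluation import (
    ConfusionCounts,
    confusion_from_summary,
    expected_correct,
    report_from_confusion,
)
from .forest_engine import grow_forest, permutation_importance
from .indicator_analysis import run_indicator
from .proximity_imputation import impute
from .synthetic_data import SyntheticConfig, generate

TIERS = ("poorly_known", "well_known", "evaluated")


@dataclass
class RunConfig:
    """Settings for a full analysis run."""

    synthetic: SyntheticConfig | None = None
    table_path: str | None = None
    metadata_path: str | None = None
    axes: tuple[str, ...] = ("rarity", "decline")
    tiers: tuple[str, ...] = TIERS
    n_trees: int = 10_000
    imputation_trees: int = 1000
    imputation_iterations: int = 10
    indicator_pairs: tuple[tuple[str, str], ...] = ()
    n_replicates: int = 10
    seed: int = 0
    output_dir: str | None = None


@dataclass
class ReportBundle:
    """All tabular outputs of one run."""

    classification: pd.DataFrame
    importances: pd.DataFrame
    indicator: pd.DataFrame
    log: list[str] = field(default_factory=list)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.classification.to_csv(out / "classification.csv", index=False)
        self.importances.to_csv(out / "importances.csv", index=False)
        self.indicator.to_csv(out / "indicator.csv", index=False)
        (out / "run.log").write_text("\n".join(self.log) + "\n", encoding="utf-8")


def _stage_seed(master: int, stage: str) -> int:
    return (int(master) * 1_000_003 + zlib.crc32(stage.encode())) & 0x7FFFFFFF


def _load_table(config: RunConfig) -> SpeciesTable:
    if config.synthetic is not None:
        table, _, _ = generate(config.synthetic)
        return table
    if not (config.table_path and config.metadata_path):
        raise ValueError("either a synthetic config or table+metadata paths required")
    table, _ = read_species_table(config.table_path, config.metadata_path)
    return table


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Run every kingdom × axis × tier classification plus indicator pairs."""
    table = _load_table(config)
    log: list[str] = [f"input: {table.n_species} species × {table.n_attributes} attributes"]
    class_rows = []
    imp_rows = []
    for kingdom in sorted(set(table.kingdom.tolist())):
        kmask = table.kingdom == kingdom
        sub = table.subset(kmask)
        for axis in config.axes:
            labels_full = sub.labels(axis)
            for tier in config.tiers:
                stage = f"{kingdom}/{axis}/{tier}"
                tiered = select_tier(sub, tier, axis=axis)
                filtered, removed = filter_attributes(tiered)
                completed = impute(
                    filtered,
                    labels_full,
                    n_trees=config.imputation_trees,
                    n_iter=config.imputation_iterations,
                    seed=_stage_seed(config.seed, stage + "/impute"),
                )
                model = grow_forest(
                    completed,
                    labels_full,
                    n_trees=config.n_trees,
                    seed=_stage_seed(config.seed, stage + "/forest"),
                )
                conf = ConfusionCounts.from_predictions(labels_full, model.oob_prediction)
                rep = report_from_confusion(conf)
                class_rows.append(
                    {
                        "kingdom": kingdom,
                        "axis": axis,
                        "tier": tier,
                        "n_species": rep.n,
                        "n_attributes": filtered.n_attributes,
                        "correct_percent": round(rep.correct_percent, 2),
                        "chi_square_p": rep.chi_square_p,
                        "type1": round(rep.type1, 3),
                        "type2": round(rep.type2, 3),
                    }
                )
                ranking = permutation_importance(
                    model, completed, labels_full,
                    seed=_stage_seed(config.seed, stage + "/importance"),
                )
                for rank, name in enumerate(ranking.top(10), start=1):
                    imp_rows.append(
                        {
                            "kingdom": kingdom, "axis": axis, "tier": tier,
                            "rank": rank, "attribute": name,
                            "importance": round(ranking[name], 6),
                        }
                    )
                log.append(
                    f"{stage}: {filtered.n_attributes} attributes "
                    f"({len(removed)} removed), correct {rep.correct_percent:.2f}%"
                )

    ind_rows = []
    for indicator, higher in config.indicator_pairs:
        res = run_indicator(
            table,
            indicator,
            higher,
            axis="decline",
            n_replicates=config.n_replicates,
            seed=_stage_seed(config.seed, f"indicator/{indicator}->{higher}"),
            n_trees=config.n_trees,
            imputation_trees=config.imputation_trees,
            imputation_iterations=config.imputation_iterations,
        )
        row = res.as_row()
        row["ci_lo"] = round(res.actual_ci[0], 2)
        row["ci_hi"] = round(res.actual_ci[1], 2)
        row["importance_overlap"] = res.importance_overlap
        ind_rows.append(row)
        log.append(
            f"indicator {indicator}->{higher}: expected {res.expected:.2f}%, "
            f"actual {res.actual_mean:.2f}%"
        )

    bundle = ReportBundle(
        classification=pd.DataFrame(class_rows),
        importances=pd.DataFrame(imp_rows),
        indicator=pd.DataFrame(ind_rows),
        log=log,
    )
    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle


# ---------------------------------------------------------------------------
# Published-summary arithmetic check
# ---------------------------------------------------------------------------

#: published decline-classification summaries of the four classical Dutch
#: indicator groups: (n, prevalence, type I, type II, printed correct %)
PUBLISHED_INDICATOR_SUMMARIES = {
    "vertebrates": (175, 0.44, 0.224, 0.494, 65.71),
    "birds": (77, 0.34, 0.176, 0.769, 62.34),
    "butterflies": (49, 0.76, 0.333, 0.054, 87.76),
    "vascular plants": (109, 0.29, 0.091, 0.625, 75.23),
}

#: published birds→vertebrates transfer: vertebrate sample size, prevalence,
#: and the printed prevalence-corrected expected correct %
PUBLISHED_BIRDS_TO_VERTEBRATES = (175, 0.44, 56.27)


def verify_reported_arithmetic() -> pd.DataFrame:
    """Re-derive published correct-% values from their printed summaries.

    For each indicator group, integer confusion counts are reconstructed
    from the printed (n, prevalence, Type I, Type II) and the implied
    correct-classification percentage recomputed; the birds row is then
    projected onto the vertebrate prevalence to reproduce the published
    expected transfer value. Returns one row per check with a ``match``
    flag (agreement to 2 decimal places).
    """
    rows = []
    confusions = {}
    for group, (n, prev, t1, t2, printed) in PUBLISHED_INDICATOR_SUMMARIES.items():
        conf, consistent = confusion_from_summary(n, prev, t1, t2)
        confusions[group] = conf
        value = round(100.0 * conf.correct, 2)
        rows.append(
            {
                "check": f"{group} correct %",
                "published": printed,
                "recomputed": value,
                "match": bool(abs(value - printed) < 0.005) and consistent,
            }
        )
    vn, vprev, printed = PUBLISHED_BIRDS_TO_VERTEBRATES
    value = round(expected_correct(confusions["birds"], vn, vprev), 2)
    rows.append(
        {
            "check": "birds->vertebrates expected correct %",
            "published": printed,
            "recomputed": value,
            "match": bool(abs(value - printed) < 0.005),
        }
    )
    return pd.DataFrame(rows)
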