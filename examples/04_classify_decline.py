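"""Grow a forest on decline labels and read its out-of-bag report.

Each species is evaluated only by the trees whose bootstrap sample
excluded it, so no holdout set is needed. The report gives the correct
classification %, the Type I error (a stable species called declining) and
Type II error (a declining species called stable), and a chi-square test
against random classification. Permutation importance then ranks the
attributes.
"""

from redlistrf import (
    ConfusionCounts,
    SyntheticConfig,
    generate,
    grow_forest,
    impute,
    permutation_importance,
    report_from_confusion,
)

table, _, truth = generate(SyntheticConfig(seed=1))
completed = impute(table, table.decline, n_trees=300, n_iter=5, seed=1)
model = grow_forest(completed, table.decline, n_trees=1000, seed=1)

conf = ConfusionCounts.from_predictions(table.decline, model.oob_prediction)
rep = report_from_confusion(conf)
print(f"OOB correct classification: {rep.correct_percent:.2f}%")
print(f"Type I error:  {rep.type1:.3f}")
print(f"Type II error: {rep.type2:.3f}")
print(f"chi-square p vs random: {rep.chi_square_p:.2e}")
print(f"Bayes ceiling: {100 * truth.bayes_accuracy:.2f}%")

top10 = permutation_importance(model, completed, table.decline, seed=1).top(10)
planted = set(truth.informative)
print("top-10 attributes (* = planted):")
for name in top10:
    print(f"  {'*' if name in planted else ' '} {name}")
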