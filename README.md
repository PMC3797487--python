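# redlistrf

Random-forest classification of species **rarity** and **decline** from
categorical trait attributes, with proximity-based missing-value
imputation, distribution-derived preference attributes, and
indicator-group transfer analysis with prevalence correction.

## The problem

National Red Lists assess only a handful of well-studied taxonomic groups,
yet conservation policy needs threat estimates for whole faunas and
floras. One route is to learn the relationship between species *traits*
(morphology, demography, habitat requirements, distribution summaries) and
binary threat labels — *rare* vs not, *declining* vs not — across many
taxonomic groups at once, and then ask two questions:

1. How well can rarity and decline be classified from attributes alone,
   and how does performance fall as less information is available
   (attribute tiers for evaluated / well-known / poorly-known species)?
2. How well does a model trained on a classical *indicator group* (birds,
   vertebrates, butterflies, vascular plants) classify the *higher
   taxonomic group* that contains it?

`redlistrf` implements this pipeline for users in conservation ecology and
trait-based modelling: ecologists with a species × attribute table and Red
List labels, and methodologists studying indicator-group transferability.

## The method

* **Attributes.** Everything is categorical (2–10 levels). Scale variables
  are cut into five equal-width ordinal bins (optionally after a log
  transform). Inapplicable nominal traits become all-zero dummy columns.
  Distribution data contribute the group-equalized phi preference
  φ_k = (f_k − f̄) / √((K−1) · f̄ · (1−f̄)) per site group k (with f_k the
  within-group occupied fraction and f̄ its mean over the K groups), the
  specialization index S = √(Σ_k φ_k²), and the logit *commonness* of the
  occupied fraction of grid cells. Attributes with >99 % of species in one
  category or >25 % missing values are dropped.
* **Imputation.** Missing cells are filled from forest *proximities* (the
  fraction of trees in which two species share a terminal node): the
  category with the largest average proximity among observed carriers
  (nominal/binary) or the proximity-weighted mean level (ordinal), grown
  with 1000 trees and iterated 10 times by default.
* **Forests.** 10,000 CART trees (Gini, grown to purity) on bootstrap
  samples, mtry = ⌊√p⌋. Evaluation is **out-of-bag**: each species is
  voted on only by trees that never saw it. Reports give the correct
  classification %, the Type I error α = FP/(FP+TN) and Type II error
  β = FN/(TP+FN) (positive class = rare/declining), linked by the exact
  identity C = (1−p)(1−α) + p(1−β) with p the prevalence, plus a Pearson
  chi-square test against random classification. Attribute rankings use
  out-of-bag permutation importance.
* **Indicator transfer.** A forest grown on the indicator group classifies
  the higher group; the *expected* correct classification re-projects the
  indicator's error rates onto the higher group's prevalence,
  100·[(1−p_h)(1−α) + p_h(1−β)], and the whole procedure is replicated
  (default 10×) for a 95 % confidence interval.
* **Synthetic data.** A generator plants known structure (informative
  attributes, per-group label noise, taxonomic signal, missingness) and
  reports the Monte-Carlo Bayes-optimal accuracy, so every stage can be
  validated absolutely without the original survey data.

## Worked example

```bash
python examples/04_classify_decline.py
```

```
OOB correct classification: 72.67%
Type I error:  0.267
Type II error: 0.280
chi-square p vs random: 1.30e-28
Bayes ceiling: 77.27%
top-10 attributes (* = planted):
  * pk_attr_005
  * wk_attr_014
  * wk_attr_013
  * commonness_1950_1990
  * ek_attr_021
  ...
```

On a 600-species synthetic table with five planted informative attributes
and 10 % label noise, the forest classifies decline correctly for 72.7 %
of species out-of-bag — within five points of the 77.3 % Bayes ceiling the
generator computes for its own labels — the classification is far from
random (chi-square p ≈ 10⁻²⁸), and all five planted attributes head the
permutation-importance ranking. The other examples cover simulation,
attribute engineering, imputation recovery, and indicator transfer; the
`redlistrf` console script (`simulate`, `run`, `indicator`, `verify`)
wraps the same library calls for shell use.

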