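# Methods

This note documents the models and procedures implemented in `redlistrf`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not
demonstrate.

## Labels

Rarity and decline are binary reductions of ordered Red List categories:
a species is *rare* when its category is "rare" or higher, *declining*
when its trend category is "moderately declining" or worse. The full
category orderings vary between national lists and species groups, so
`RedListMapping` is configuration-driven; only the two thresholds are
fixed defaults. Both labels are treated as ground truth — the method
relates them to attributes, it does not re-derive them.

## Attribute engineering

**Categorization.** All predictors are categorical so that attribute
importance is not inflated by cardinality differences. Scale variables are
discretized into five equal-width bins over the observed range of the
analysis subset, after an optional log transform for right-skewed
quantities. Which raw variables are log-transformed is a per-attribute
choice exposed in configuration. Ties on an interior bin edge go to the
lower bin and the global maximum goes to the top bin, making the
discretization deterministic. Derived scale attributes (phi,
specialization, commonness) pass through the same five-level binning
before modelling.

**Inapplicable traits.** A nominal trait that is meaningless for part of
the species set (water-flow preference for terrestrial species) becomes
one dummy column per level, with inapplicable species zero in every dummy
and missing species missing in every dummy.

**Distribution attributes.** For a site-grouping scheme with K groups
(land-use categories, physio-geographical regions), the group-equalized
phi of a species' presence against group k is

    φ_k = (f_k − f̄) / sqrt((K − 1) · f̄ · (1 − f̄)),

with f_k the occupied fraction of group-k sites and f̄ the mean of the
f_j. This equals the classical 2×2 phi between presence and group-k
membership computed after every group is reweighted to equal size (the
property test verifies this equivalence against a brute-force replicated
contingency table to 12 decimals). A species present in all sites or none
(f̄ ∈ {0, 1}) carries no preference information; its profile is defined
as zero rather than undefined. Specialization is the Euclidean norm of
the phi profile. Commonness is the logit of the occupied fraction of
group-observed grid cells with a Haldane correction,
p′ = (a + 0.5)/(N + 1), chosen to keep the endpoints finite with minimal
distortion; the source analysis does not state its endpoint handling.
Commonness is excluded from rarity analyses because present-day rarity is
itself a function of occupied range — the attribute would leak the label.

**Filtering.** Attributes with strictly more than 99 % of non-missing
values in one category are uninformative; attributes with strictly more
than 25 % missing values would make imputation a liability. Both rules
are evaluated on the species subset entering the analysis, and filtering
is idempotent.

## Proximity imputation

Missing cells are initialized with the attribute mode (binary/nominal) or
median level (ordinal). Each iteration grows a forest on the completed
table (label-aware by default: the class labels are the response, as in
the classical bagged-tree missing-data routine; an unsupervised
real-vs-scrambled mode is available), computes proximities over all
cases, and re-estimates every *originally* missing cell from the species
whose value was actually observed:

* nominal/binary — the category with the largest **average** proximity
  among its observed carriers. Normalizing by carrier count matters: a
  raw proximity sum is biased toward globally common categories, and in
  measured comparisons the average rule lifts recovery of a duplicated
  label-informative attribute from ~70 % to ~97 %.
* ordinal — the proximity-weighted mean level, rounded half-up and
  clipped to the level range.

Observed cells are never altered; the defaults (1000 trees, 10
iterations) follow the study procedure. Ties in the category vote break
toward the lowest code, and a row with no proximity mass keeps its
current fill, so the procedure is deterministic given the seed.

Two empirical caveats, established with both this implementation and the
reference R routine on identical data: proximity mass is diffuse (label
purity, not attribute similarity, shapes the terminal nodes), so (a) a
single duplicated species does *not* reliably dominate the vote for its
twin's masked cell when the masked value is globally rare, and (b)
recovery of an ordinal attribute by weighted-mean-and-round shrinks
toward the middle level. High recovery is realistic mainly for attributes
that the trees actually split on — i.e. label-informative ones — which is
the regime the recovery tests use.

## Forests

Trees are CART classifiers (Gini impurity, grown to purity, minimum node
size 1) on bootstrap samples of size n drawn with replacement; each node
evaluates ⌊√p⌋ randomly chosen encoded columns. Ordinals and binaries
enter as single integer-coded columns (splits are level thresholds);
nominals with ≥3 levels are one-hot encoded because threshold splits on
arbitrary level codes would impose a spurious order — the encoding is
recorded in the model summary. The bagging loop is implemented in-package
(over scikit-learn trees) because out-of-bag voting, proximities, and
per-tree permutation importance all need the bootstrap membership of
every tree.

Out-of-bag prediction is the majority vote of the trees whose bootstrap
excluded the species; vote ties break toward the negative class
(conservative: a tie never labels a species threatened). The default
forest size is 10,000 trees; OOB accuracy on the default synthetic table
moves by well under one percentage point between 1000- and 2000-tree
forests, which is the scaled form of the stability check used throughout
the test suite.

Permutation importance is the raw mean decrease, over trees, in the
fraction of a tree's out-of-bag species classified correctly after the
attribute's values are permuted among them (all one-hot columns of a
nominal move together). It is reported unscaled, per the source
procedure; top-10 ties break by attribute name for determinism. An
attribute a tree never split on contributes exactly zero for that tree.

## Evaluation

With the positive class rare/declining: correct classification
C = (TP+TN)/n, Type I error α = FP/(FP+TN), Type II error β = FN/(TP+FN),
prevalence p = (TP+FN)/n, and the exact identity
C = (1−p)(1−α) + p(1−β). Published summary rows (n, p, α, β) are inverted
to integer confusion counts by half-up rounding — positives = round(p·n),
FP = round(α·negatives), FN = round(β·positives) — which reproduces all
four published indicator-group correct-percentages to 2 d.p.; a
consistency flag marks summaries whose exact recomputed rates deviate by
more than 0.01.

The prevalence-corrected expected correct classification projects an
indicator's exact error-rate ratios onto a higher group with prevalence
p_h (snapped to an integer positive count):
C_exp = 100·[(1−p_h)(1−α) + p_h(1−β)]. Its explicit form was derived from
the identity above; it reproduces the published birds→vertebrates
expected value (56.27 %) exactly. For the other published transfer rows
the higher groups' exact positive counts are not recoverable from the
rounded printed prevalences, so no values are asserted for them.

Chi-square tests are plain Pearson on 2×2 tables, 1 d.f., no continuity
correction (a Yates option exists because some environments apply it by
default); a zero marginal returns p = 1 with a degeneracy flag. The
statistic is computed in closed form, with scipy supplying only the tail
probability; agreement with `scipy.stats.chi2_contingency` is tested to
6 decimals.

## Indicator transfer

Per replicate: the higher-group table is imputed (label-aware), a forest
is grown on the indicator rows only, its OOB confusion gives α, β and the
expected value at the evaluated sample's prevalence, and the forest then
predicts the evaluated higher-group rows. Replicates (default 10) rerun
imputation and forest growth with seeds derived deterministically from
the master seed; the actual correct % is summarized by a Student-t 95 %
interval over replicates (the error-bar construction was not specified in
the source; ±1.96·sd is available as an option). The expected value is
recomputed per replicate and averaged. The top-10 importance overlap
between the indicator forest and a full higher-group forest is computed
per replicate; the reported integer is the half-up-rounded mean.

The evaluated sample includes the indicator's own rows by default,
mirroring the published design; this is optimistic for those rows (the
forest saw them in training), and `include_indicator_rows=False` scores
only the unseen species. The replicate interval reflects *procedural*
randomness only — forest and imputation draws on a fixed dataset. It is
necessarily narrower than the dataset-to-dataset sampling variation of
actual-vs-expected, so the null check "expected falls inside the
replicate interval" is run under conditions where both quantities
converge: a noiseless single-attribute rule shared by indicator and
higher group, with site groups drawn from near-identical attribute
distributions. Under label noise or group-level distribution shift the
two quantities genuinely separate (OOB error rates are also mildly
pessimistic), which is a property of the statistic, not an implementation
artifact — and is exactly the phenomenon the transfer analysis exists to
measure.

## Synthetic data

The generator emulates the statistical shape of a national Red List trait
dataset: nested groups (kingdom → class → order) with sizes given by a
group tree (default 600 species in 7 leaf groups; a preset reproduces the
1183-species / 18-group / 152-attribute / three-tier shape with decline
and rarity prevalences near 0.46 and 0.57); binary / five-level ordinal /
nominal attributes in ratio 5:4:1 across three availability tiers (8 / 12
/ 10 introduced per tier by default); group structure from
Dirichlet-perturbed per-group category distributions (concentration 25 by
default — lower is stronger taxonomic signal); decline labels from a
logistic model on five informative attributes (effect size 1.5 sd per
attribute, intercept calibrated by bisection to a target prevalence of
0.5) or from an alternating AND/OR rule list; per-group label-noise flips
(default 0.1); MCAR missingness per tier (default 0.1); and an occupancy
table whose per-species site-group preferences are correlated with
decline. A past-commonness attribute (evaluated tier, five levels) is
always among the informative set for decline, mirroring the robust
empirical association between past range and decline. Ground truth
records the planted attributes and weights and a 100,000-draw Monte-Carlo
estimate of the Bayes-optimal accuracy, E[max(q, 1−q)] over the post-noise
class probability q.

What it does not emulate: real phylogenetic trait covariance (group
structure is marginal, not tree-shaped), informative missingness,
geographic autocorrelation in the occupancy grid, or expert-questionnaire
biases. Passing tests therefore show that the pipeline recovers planted
signal under the stated noise model, not that real Dutch percentages
would be reproduced.

## Problem sizes and numerical choices

Library defaults follow the study procedure (10,000-tree forests;
1000-tree, 10-iteration imputation). The test and acceptance suites run
the same code at reduced sizes chosen as the package's own
test-scale conditions: 100–1000-tree forests, 100–500-tree / 2–5-iteration
imputation, tables of 60–600 species. All randomness flows from explicit
integer seeds (numpy `SeedSequence`; per-stage seeds derive from a CRC of
the stage name, kept below 2³¹), and every reported experiment is
bit-reproducible from its configuration and master seed.

Known limitations: no multiple-imputation uncertainty propagation; no
probability calibration of vote fractions; unscaled importance only; the
ordinal imputation rule shrinks toward central levels (see above);
single-threaded by design to keep determinism trivial.
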