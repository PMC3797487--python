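"""Random forests of classification trees with out-of-bag machinery.

Each tree is a CART classifier (Gini impurity, grown to purity) fitted on a
bootstrap sample of the species, testing ``floor(sqrt(p))`` randomly chosen
encoded columns at each node. The bagging loop is implemented here rather
than delegated to an off-the-shelf ensemble because the method needs three
things ensembles rarely expose together: per-tree bootstrap membership (for
out-of-bag voting), case proximities (fraction of trees in which two species
share a terminal node — the basis of the imputation scheme), and per-tree
out-of-bag permutation importance (mean decrease in OOB correct
classification).

Ordinal and binary attributes enter as single integer-coded columns (splits
are level thresholds); nominal attributes with three or more levels are
one-hot encoded, since threshold splits on arbitrary level codes would
impose a spurious order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .data_model import MISSING, AttributeSpec, SpeciesTable, ValidationError

DEFAULT_N_TREES = 10_000


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableEncoder:
    """Maps a species table to the numeric model matrix trees split on."""

    specs: tuple[AttributeSpec, ...]
    #: per encoded column: (attribute index, one-hot level or None)
    columns: tuple[tuple[int, int | None], ...]

    @classmethod
    def from_specs(cls, specs) -> "TableEncoder":
        columns: list[tuple[int, int | None]] = []
        for j, spec in enumerate(specs):
            if spec.kind == "nominal" and spec.n_categories >= 3:
                columns.extend((j, lev) for lev in range(spec.n_categories))
            else:
                columns.append((j, None))
        return cls(specs=tuple(specs), columns=tuple(columns))

    @property
    def n_encoded(self) -> int:
        return len(self.columns)

    def encode(self, values: np.ndarray) -> np.ndarray:
        if (values == MISSING).any():
            raise ValidationError("table has missing cells; impute first")
        X = np.empty((values.shape[0], self.n_encoded), dtype=np.float32)
        for c, (j, lev) in enumerate(self.columns):
            col = values[:, j]
            X[:, c] = col if lev is None else (col == lev)
        return X

    def attribute_slices(self) -> dict[str, np.ndarray]:
        """Encoded column indices belonging to each attribute."""
        out: dict[str, list[int]] = {s.name: [] for s in self.specs}
        for c, (j, _) in enumerate(self.columns):
            out[self.specs[j].name].append(c)
        return {k: np.asarray(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class ForestModel:
    """A fitted forest with its bootstrap bookkeeping.

    ``inbag`` is the (n_trees × n_species) boolean in-bag matrix;
    ``oob_votes`` counts, per training species, the votes of trees whose
    bootstrap sample excluded it.
    """

    trees: list
    encoder: TableEncoder
    inbag: np.ndarray
    oob_votes: np.ndarray
    n_trees: int
    mtry: int
    seed: int
    attribute_names: list[str] = field(default_factory=list)

    @property
    def oob_prediction(self) -> np.ndarray:
        """Majority OOB vote per species; ties go to the negative class."""
        return (self.oob_votes[:, 1] > self.oob_votes[:, 0]).astype(np.int8)

    @property
    def oob_vote_fraction(self) -> np.ndarray:
        tot = self.oob_votes.sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(tot > 0, self.oob_votes[:, 1] / np.maximum(tot, 1), np.nan)

    def oob_coverage(self) -> np.ndarray:
        """Number of OOB trees per training species."""
        return self.oob_votes.sum(axis=1).astype(int)

    def summary(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "mtry": self.mtry,
            "seed": self.seed,
            "n_encoded_columns": self.encoder.n_encoded,
            "nominal_encoding": "one-hot",
        }


@dataclass
class ImportanceRanking:
    """Permutation importances with a deterministic rank order.

    Importance is the raw mean decrease, over trees, in the fraction of a
    tree's out-of-bag species it classifies correctly when one attribute's
    values are permuted. Ties in the ranking break by attribute name.
    """

    names: list[str]
    importance: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"attribute": self.names, "importance": self.importance})
        return df.sort_values(
            ["importance", "attribute"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)

    def top(self, k: int = 10) -> list[str]:
        return self.as_frame()["attribute"].head(k).tolist()

    def __getitem__(self, name: str) -> float:
        return float(self.importance[self.names.index(name)])


# ---------------------------------------------------------------------------
# Growing and predicting
# ---------------------------------------------------------------------------

def _tree_seeds(seed: int, n_trees: int) -> tuple[np.random.Generator, np.ndarray]:
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF]))
    return rng, rng.integers(0, 2**31 - 1, size=n_trees)


def grow_forest(
    table: SpeciesTable,
    labels: np.ndarray,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> ForestModel:
    """Grow a bagged ensemble of Gini trees on a complete species table.

    Each tree sees a size-n bootstrap sample drawn with replacement and
    tests ``floor(sqrt(p))`` random encoded columns per node; trees are
    grown to purity (minimum node size 1). Out-of-bag votes are accumulated
    during fitting.
    """
    labels = np.asarray(labels).astype(np.int8)
    if len(labels) != table.n_species:
        raise ValidationError("labels length does not match table")
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < 2:
        raise ValidationError("need at least 2 species in each class")
    encoder = TableEncoder.from_specs(table.specs)
    X = encoder.encode(table.values)
    n = X.shape[0]
    mtry = max(1, int(math.isqrt(encoder.n_encoded)))

    rng, tree_seeds = _tree_seeds(seed, n_trees)
    trees = []
    inbag = np.zeros((n_trees, n), dtype=bool)
    oob_votes = np.zeros((n, 2), dtype=np.int32)
    all_idx = np.arange(n)
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        inbag[t, boot] = True
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=mtry,
            min_samples_leaf=1,
            random_state=int(tree_seeds[t]),
        )
        tree.fit(X[boot], labels[boot])
        oob = all_idx[~inbag[t]]
        if len(oob):
            pred = _predict_binary(tree, X[oob])
            oob_votes[oob, 0] += pred == 0
            oob_votes[oob, 1] += pred == 1
        trees.append(tree)
    return ForestModel(
        trees=trees,
        encoder=encoder,
        inbag=inbag,
        oob_votes=oob_votes,
        n_trees=n_trees,
        mtry=mtry,
        seed=int(seed),
        attribute_names=table.attribute_names,
    )


def _predict_binary(tree: DecisionTreeClassifier, X: np.ndarray) -> np.ndarray:
    """Tree prediction mapped onto the global {0, 1} label space."""
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    proba = tree.tree_.predict(X32)
    if proba.ndim == 3:  # (n, n_outputs, n_classes) in some sklearn versions
        proba = proba[:, 0, :]
    return tree.classes_[np.argmax(proba, axis=1)].astype(np.int8)


def predict(model: ForestModel, table: SpeciesTable) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote of all trees; returns (labels, positive-vote fractions).

    Vote ties break toward the negative (not rare / not declining) class.
    """
    if table.attribute_names != model.attribute_names:
        raise ValidationError("table attributes do not match the fitted model")
    X = model.encoder.encode(table.values)
    votes = np.zeros((X.shape[0], 2), dtype=np.int32)
    for tree in model.trees:
        pred = _predict_binary(tree, X)
        votes[:, 0] += pred == 0
        votes[:, 1] += pred == 1
    frac = votes[:, 1] / model.n_trees
    return (votes[:, 1] > votes[:, 0]).astype(np.int8), frac


def oob_correct_fraction(model: ForestModel, labels: np.ndarray) -> float:
    """Fraction of species (with ≥1 OOB tree) whose OOB vote is correct."""
    labels = np.asarray(labels)
    covered = model.oob_coverage() > 0
    if not covered.any():
        raise ValidationError("no species has out-of-bag coverage")
    return float((model.oob_prediction[covered] == labels[covered]).mean())


# ---------------------------------------------------------------------------
# Proximities
# ---------------------------------------------------------------------------

def proximity_matrix(model: ForestModel, table: SpeciesTable) -> np.ndarray:
    """Pairwise proximities: fraction of trees sharing a terminal node.

    Computed over all cases (in-bag and out-of-bag). Symmetric with unit
    diagonal.
    """
    X = model.encoder.encode(table.values)
    n = X.shape[0]
    prox = np.zeros((n, n), dtype=np.float32)
    for tree in model.trees:
        leaves = tree.apply(X)
        prox += leaves[:, None] == leaves[None, :]
    prox /= model.n_trees
    return prox


# ---------------------------------------------------------------------------
# Permutation importance
# ---------------------------------------------------------------------------

def permutation_importance(
    model: ForestModel,
    table: SpeciesTable,
    labels: np.ndarray,
    seed: int = 0,
) -> ImportanceRanking:
    """Out-of-bag permutation importance per attribute.

    For every tree, its OOB species are classified once as-is and once with
    the attribute's values permuted among those species (all one-hot columns
    of a nominal attribute move together); the importance is the mean
    per-tree drop in OOB correct-classification fraction. An attribute a
    tree never split on contributes exactly zero for that tree.
    """
    labels = np.asarray(labels).astype(np.int8)
    X = model.encoder.encode(table.values)
    slices = model.encoder.attribute_slices()
    names = model.attribute_names
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5EED]))
    total = np.zeros(len(names))
    n_used = 0
    for t, tree in enumerate(model.trees):
        oob = np.flatnonzero(~model.inbag[t])
        if len(oob) == 0:
            continue
        n_used += 1
        Xo = X[oob]
        yo = labels[oob]
        base = float((_predict_binary(tree, Xo) == yo).sum())
        # features the tree actually split on — others contribute 0 exactly
        used_cols = set(tree.tree_.feature[tree.tree_.feature >= 0].tolist())
        for a, name in enumerate(names):
            cols = slices[name]
            if not any(int(c) in used_cols for c in cols):
                continue
            perm = rng.permutation(len(oob))
            Xp = Xo.copy()
            Xp[:, cols] = Xo[np.ix_(perm, cols)]
            dropped = base - float((_predict_binary(tree, Xp) == yo).sum())
            total[a] += dropped / len(oob)
    if n_used == 0:
        raise ValidationError("no tree has out-of-bag cases")
    return ImportanceRanking(names=list(names), importance=total / n_used)
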