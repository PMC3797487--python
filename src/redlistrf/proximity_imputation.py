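"""Iterated proximity-based imputation of missing attribute values.

Missing cells are first filled crudely (mode for binary/nominal, median
level for ordinal). A forest is then grown on the completed table and the
case proximities — the fraction of trees in which two species land in the
same terminal node — are used to re-estimate every originally missing cell
from the species whose value was actually observed: a proximity-weighted
category vote for nominal/binary attributes, a proximity-weighted mean level
rounded to the nearest integer for ordinals. Growing and re-estimating are
iterated so the fills sharpen as the proximities improve. Originally
observed cells are never altered.

By default the imputation forests are label-aware (they use the rarity or
decline labels as the response, like the classical missing-data routine of
bagged-tree packages); an unsupervised mode builds a two-class forest that
separates the real table from a column-scrambled copy and uses the real-row
proximities instead.
"""

from __future__ import annotations

import numpy as np

from .data_model import MISSING, SpeciesTable, ValidationError
from .forest_engine import TableEncoder, grow_forest, proximity_matrix


def _initial_fill(table: SpeciesTable) -> np.ndarray:
    values = table.values.copy()
    for j, spec in enumerate(table.specs):
        col = values[:, j]
        obs = col != MISSING
        if not obs.any():
            raise ValidationError(
                f"attribute {spec.name!r} has no observed values; filter it out first"
            )
        if spec.kind == "ordinal":
            fill = int(np.floor(np.median(col[obs]) + 0.5))
        else:
            counts = np.bincount(col[obs], minlength=spec.n_categories)
            fill = int(np.argmax(counts))  # tie -> lowest code
        col[~obs] = fill
    return values


def _reestimate(
    values: np.ndarray,
    table: SpeciesTable,
    prox: np.ndarray,
    missing: np.ndarray,
) -> np.ndarray:
    """One proximity-weighted update of the originally missing cells."""
    out = values.copy()
    for j, spec in enumerate(table.specs):
        miss_rows = np.flatnonzero(missing[:, j])
        if len(miss_rows) == 0:
            continue
        obs_rows = np.flatnonzero(~missing[:, j])
        W = prox[np.ix_(miss_rows, obs_rows)].astype(np.float64)
        wsum = W.sum(axis=1)
        ok = wsum > 0  # rows with no proximity mass keep their current fill
        obs_vals = table.values[obs_rows, j]
        if spec.kind == "ordinal":
            est = W[ok] @ obs_vals / wsum[ok]
            new = np.floor(est + 0.5).astype(np.int16)  # half-up
            new = np.clip(new, 0, spec.n_categories - 1)
        else:
            # category with the largest *average* proximity among its
            # observed carriers (normalising by carrier count removes the
            # base-rate bias a raw proximity sum would have)
            onehot = np.zeros((len(obs_rows), spec.n_categories))
            onehot[np.arange(len(obs_rows)), obs_vals] = 1.0
            counts = onehot.sum(axis=0)
            scores = W[ok] @ onehot
            with np.errstate(invalid="ignore", divide="ignore"):
                scores = np.where(counts > 0, scores / counts, -np.inf)
            new = np.argmax(scores, axis=1).astype(np.int16)  # tie -> lowest code
        out[miss_rows[ok], j] = new
    return out


def impute(
    table: SpeciesTable,
    labels: np.ndarray | None = None,
    n_trees: int = 1000,
    n_iter: int = 10,
    seed: int = 0,
    label_aware: bool = True,
) -> SpeciesTable:
    """Return a complete copy of ``table`` with missing cells imputed.

    Parameters
    ----------
    table : SpeciesTable
        Table with integer-coded values and ``-1`` for missing cells.
    labels : array of 0/1
        Class labels, required when ``label_aware`` (the default); the
        imputation forests are grown against them.
    n_trees : int
        Trees per imputation forest (1000 matches the study procedure).
    n_iter : int
        Grow/re-estimate iterations (10 matches the study procedure).
    seed : int
        Master seed; per-iteration forest seeds derive deterministically.
    label_aware : bool
        If False, use an unsupervised real-vs-scrambled forest instead of
        the class labels.

    A table without missing cells is returned unchanged (no forests grown).
    """
    if table.n_species == 0:
        raise ValidationError("empty table")
    missing = table.missing_mask
    if not missing.any():
        return table.copy()
    if label_aware:
        if labels is None:
            raise ValidationError("labels are required for label-aware imputation")
        labels = np.asarray(labels).astype(np.int8)
        if len(labels) != table.n_species:
            raise ValidationError("labels length does not match table")

    values = _initial_fill(table)
    work = table.copy()
    for it in range(n_iter):
        work.values = values
        it_seed = (int(seed) + it) & 0x7FFFFFFF
        if label_aware:
            model = grow_forest(work, labels, n_trees=n_trees, seed=it_seed)
            prox = proximity_matrix(model, work)
        else:
            prox = _unsupervised_proximity(work, n_trees=n_trees, seed=it_seed)
        values = _reestimate(values, table, prox, missing)
    out = table.copy()
    out.values = values
    assert not (out.values == MISSING).any()
    return out


def _unsupervised_proximity(table: SpeciesTable, n_trees: int, seed: int) -> np.ndarray:
    """Proximities from a forest separating the table from a scrambled copy.

    The synthetic contrast class permutes each column independently, which
    destroys between-attribute structure while keeping marginals; real-row
    proximities from that forest reflect joint attribute similarity.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5CA1]))
    n = table.n_species
    scrambled = np.column_stack(
        [rng.permutation(table.values[:, j]) for j in range(table.n_attributes)]
    ).astype(table.values.dtype)
    both = table.copy()
    both.species_ids = table.species_ids + [f"__scrambled_{i}" for i in range(n)]
    both.kingdom = np.concatenate([table.kingdom, table.kingdom])
    both.group = np.concatenate([table.group, table.group])
    both.values = np.vstack([table.values, scrambled])
    both.rarity = None
    both.decline = None
    y = np.concatenate([np.ones(n, dtype=np.int8), np.zeros(n, dtype=np.int8)])
    model = grow_forest(both, y, n_trees=n_trees, seed=seed)
    prox = proximity_matrix(model, both)
    return prox[:n, :n]
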