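"""Synthetic species-attribute data with planted, known structure.

The generator emulates the statistical shape of a national Red List trait
dataset: ~10²–10³ species in nested taxonomic groups (kingdom → class →
order), a few dozen to ~150 categorical/ordinal attributes in three nested
availability tiers, moderate MCAR missingness, and binary decline/rarity
labels whose prevalence is calibrated near one half.

Labels follow either a logistic model on a small set of *informative*
attributes or an interaction rule list (forests should excel on both), then
flip with a per-group label-noise probability. Taxonomic structure is
induced by Dirichlet-perturbing each attribute's category distribution per
group — related species look alike without any explicit phylogeny. A
distribution-derived "commonness" attribute (evaluated tier only) is made
informative for decline, mirroring how past commonness predicts decline in
real data. The ground truth records the planted attributes, weights, and a
Monte-Carlo estimate of the Bayes-optimal accuracy, so recovery of signal
by the pipeline can be scored absolutely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attribute_engineering import OccupancyTable
from .data_model import MISSING, AttributeSpec, SpeciesTable, ValidationError

#: default nested group tree: kingdom -> {subgroup -> {leaf: size}} or {leaf: size}
DEFAULT_GROUP_TREE = {
    "animalia": {
        "vertebrata": {"aves": 80, "other_vertebrates": 70},
        "insecta": {"lepidoptera": 60, "other_insects": 90},
    },
    "plantae": {"vascular_plants": 120, "bryophytes": 60},
    "fungi": {"macrofungi": 120},
}


@dataclass
class SyntheticConfig:
    """Generator settings; defaults give a 600-species, 30-attribute table.

    ``n_attributes_per_tier`` counts the attributes *introduced at* each
    tier (tiers are cumulative when selected). ``kind_mix`` gives the
    (binary, ordinal, nominal) attribute shares. ``label_noise`` may be a
    scalar or a {group: rate} mapping (kingdom, subgroup, or leaf labels
    accepted); ``missing_rate`` likewise per tier.
    """

    n_species: int = 600
    group_tree: dict = field(default_factory=lambda: DEFAULT_GROUP_TREE)
    n_attributes_per_tier: dict = field(
        default_factory=lambda: {"poorly_known": 8, "well_known": 12, "evaluated": 10}
    )
    kind_mix: tuple[float, float, float] = (0.5, 0.4, 0.1)
    n_informative: int = 5
    effect_model: str = "logistic"  # or "rules"
    effect_size: float = 1.5
    #: restrict planted informative attributes to these kinds (None = any)
    informative_kinds: tuple[str, ...] | None = None
    label_noise: float | dict = 0.1
    missing_rate: float | dict = 0.1
    target_prevalence: float | None = 0.5  # None: no intercept calibration
    rarity_prevalence: float = 0.55
    n_sites: int = 100
    n_site_groups: int = 4
    base_occupancy: float = 0.3
    preference_strength: float = 0.5
    group_concentration: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.n_attributes_per_tier.values())
        if self.n_informative > total:
            raise ValidationError("n_informative exceeds total attributes")
        if isinstance(self.label_noise, (int, float)) and not 0 <= self.label_noise < 0.5:
            raise ValidationError("label_noise must be in [0, 0.5)")
        if isinstance(self.missing_rate, (int, float)) and not 0 <= self.missing_rate <= 0.4:
            raise ValidationError("missing_rate must be in [0, 0.4]")

    @classmethod
    def redlist_scale(cls, seed: int = 0) -> "SyntheticConfig":
        """Preset matching the shape of the Dutch Red List trait dataset:

        1183 species in 18 leaf groups under three kingdoms, 152 attributes
        in tiers of cumulative size 40 / 88 / 152, ≤25 % missingness, and
        decline/rarity prevalences near 0.46 / 0.57.
        """
        animals = {
            "vertebrata": {
                "aves": 77, "mammalia": 35, "reptilia": 7, "amphibia": 16, "pisces": 40,
            },
            "insecta": {
                "lepidoptera": 49, "odonata": 40, "orthoptera": 30,
                "coleoptera": 90, "other_insects": 162,
            },
            "mollusca": {"gastropoda": 50, "bivalvia": 26},
        }
        plants = {
            "tracheophyta": {"vascular_plants": 109, "ferns": 23},
            "bryophyta": {"mosses": 60, "liverworts": 30},
        }
        fungi = {"basidiomycota": {"agarics": 180, "other_fungi": 159}}
        return cls(
            n_species=1183,
            group_tree={"animalia": animals, "plantae": plants, "fungi": fungi},
            n_attributes_per_tier={"poorly_known": 40, "well_known": 48, "evaluated": 64},
            n_informative=12,
            label_noise=0.15,
            missing_rate={"poorly_known": 0.05, "well_known": 0.15, "evaluated": 0.22},
            target_prevalence=0.46,
            rarity_prevalence=0.57,
            seed=seed,
        )


@dataclass
class GroundTruth:
    """What the generator planted, for scoring recovery."""

    informative: list[str]
    weights: dict[str, float]
    intercept: float
    rule_description: str
    bayes_accuracy: float
    realized_prevalence: float
    rarity_informative: list[str]
    realized_rarity_prevalence: float
    label_noise: dict


def _flatten_tree(tree: dict) -> tuple[list[tuple[str, str, str, int]], dict[str, str]]:
    """(kingdom, subgroup, leaf, size) rows plus child → parent links."""
    rows = []
    parents: dict[str, str] = {}
    for kingdom, sub in tree.items():
        for name, val in sub.items():
            if isinstance(val, dict):
                parents[name] = kingdom
                for leaf, size in val.items():
                    parents[leaf] = name
                    rows.append((kingdom, name, leaf, int(size)))
            else:
                parents[name] = kingdom
                rows.append((kingdom, name, name, int(val)))
    return rows, parents


def _per_group(value, kingdom: str, subgroup: str, leaf: str, default: float) -> float:
    if isinstance(value, dict):
        for key in (leaf, subgroup, kingdom):
            if key in value:
                return float(value[key])
        return default
    return float(value)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def generate(
    config: SyntheticConfig,
) -> tuple[SpeciesTable, OccupancyTable, GroundTruth]:
    """Draw a full synthetic dataset; deterministic in (config, seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF]))
    rows, parents = _flatten_tree(config.group_tree)
    sizes = np.array([r[3] for r in rows])
    if sizes.sum() != config.n_species:
        raise ValidationError(
            f"group tree sizes sum to {sizes.sum()}, expected n_species={config.n_species}"
        )
    kingdom = np.repeat([r[0] for r in rows], sizes).astype(object)
    subgroup = np.repeat([r[1] for r in rows], sizes)
    leaf = np.repeat([r[2] for r in rows], sizes).astype(object)
    n = config.n_species
    species_ids = [f"sp{i:05d}" for i in range(n)]

    # -- attribute specs --------------------------------------------------
    specs: list[AttributeSpec] = []
    tier_list = ("poorly_known", "well_known", "evaluated")
    for tier in tier_list:
        count = config.n_attributes_per_tier.get(tier, 0)
        for i in range(count):
            u = rng.random()
            if tier == "evaluated" and i == count - 1:
                # distribution-derived past-commonness attribute, 5-level
                specs.append(
                    AttributeSpec(
                        name="commonness_1950_1990", kind="ordinal", n_categories=5,
                        tier="evaluated", derivation="commonness",
                    )
                )
                continue
            if u < config.kind_mix[0]:
                kind, k = "binary", 2
            elif u < config.kind_mix[0] + config.kind_mix[1]:
                kind, k = "ordinal", 5
            else:
                kind, k = "nominal", int(rng.integers(3, 5))
            specs.append(
                AttributeSpec(
                    name=f"{tier[0]}k_attr_{len(specs):03d}", kind=kind,
                    n_categories=k, tier=tier, derivation="raw",
                )
            )

    # -- group-structured categorical draws -------------------------------
    leaf_names = [r[2] for r in rows]
    values = np.empty((n, len(specs)), dtype=np.int16)
    for j, spec in enumerate(specs):
        k = spec.n_categories
        base = rng.dirichlet(np.full(k, 2.0))
        for leaf_name in leaf_names:
            mask = leaf == leaf_name
            probs = rng.dirichlet(base * config.group_concentration)
            values[mask, j] = rng.choice(k, size=int(mask.sum()), p=probs)

    # -- informative attributes and decline labels ------------------------
    # spread planted signal across tiers (some in each), commonness always in
    names = [s.name for s in specs]
    kinds_ok = config.informative_kinds
    by_tier = {
        t: [
            s.name
            for s in specs
            if s.tier == t
            and s.derivation == "raw"
            and (kinds_ok is None or s.kind in kinds_ok)
        ]
        for t in tier_list
    }
    n_inf = config.n_informative
    # spread planted signal across tiers, favouring the richer tiers
    quota = {"poorly_known": 0, "well_known": 0, "evaluated": 0}
    rr = ("evaluated", "well_known", "poorly_known")
    for i in range(n_inf):
        quota[rr[i % 3]] += 1
    informative: list[str] = []
    for t in tier_list:
        take = min(quota.get(t, 0), len(by_tier[t]))
        informative.extend(
            sorted(rng.choice(by_tier[t], size=take, replace=False).tolist())
        )
    if "commonness_1950_1990" in names and quota["evaluated"] > 0 and informative:
        # make commonness one of the evaluated-tier informative attributes
        informative[-1] = "commonness_1950_1990"
    informative = sorted(set(informative))

    centered = {}
    for name in informative:
        col = values[:, names.index(name)].astype(float)
        sd = col.std()
        centered[name] = (col - col.mean()) / (sd if sd > 0 else 1.0)

    weights: dict[str, float] = {}
    sign = 1.0
    for name in informative:
        weights[name] = sign * config.effect_size
        sign = -sign

    if config.effect_model == "logistic":
        z0 = np.sum([w * centered[a] for a, w in weights.items()], axis=0)
        rule_desc = "logistic({})".format(
            " + ".join(f"{w:+.2f}*{a}" for a, w in weights.items())
        )
    elif config.effect_model == "rules":
        # interaction rule list: pairwise AND/OR of thresholded informative attrs
        feats = [centered[a] > 0 for a in informative]
        acc = feats[0]
        for i in range(1, len(feats)):
            acc = (acc & feats[i]) if i % 2 else (acc | feats[i])
        z0 = np.where(acc, 12.0, -12.0)
        rule_desc = "alternating AND/OR rule over " + ", ".join(informative)
    else:
        raise ValidationError(f"unknown effect model {config.effect_model!r}")

    noise = np.array(
        [
            _per_group(config.label_noise, kingdom[i], subgroup[i], leaf[i], 0.1)
            for i in range(n)
        ]
    )

    def _prevalence_at(b: float) -> float:
        p = _sigmoid(z0 + b) if len(informative) else np.full(n, _sigmoid(b))
        return float(np.mean(p * (1 - noise) + (1 - p) * noise))

    if config.target_prevalence is None:
        intercept = 0.0
    else:
        lo, hi = -20.0, 20.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if _prevalence_at(mid) < config.target_prevalence:
                lo = mid
            else:
                hi = mid
        intercept = 0.5 * (lo + hi)
    p_clean = (
        _sigmoid(z0 + intercept) if len(informative) else np.full(n, _sigmoid(intercept))
    )
    y_clean = (rng.random(n) < p_clean).astype(np.int8)
    flip = rng.random(n) < noise
    decline = np.where(flip, 1 - y_clean, y_clean).astype(np.int8)

    # -- rarity labels: separate logistic on a shifted attribute set ------
    rarity_pool = [a for a in informative if a != "commonness_1950_1990"]
    extra = [a for a in by_tier["well_known"] if a not in rarity_pool]
    if extra:
        rarity_pool = rarity_pool + [extra[0]]
    r_weights = {a: ((-1.0) ** i) * config.effect_size for i, a in enumerate(rarity_pool)}
    zr = (
        np.sum(
            [
                w * centered.get(a, _centered_col(values, names, a))
                for a, w in r_weights.items()
            ],
            axis=0,
        )
        if rarity_pool
        else np.zeros(n)
    )

    def _rar_prev(b: float) -> float:
        p = _sigmoid(zr + b)
        return float(np.mean(p * (1 - noise) + (1 - p) * noise))

    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _rar_prev(mid) < config.rarity_prevalence:
            lo = mid
        else:
            hi = mid
    yr = (rng.random(n) < _sigmoid(zr + 0.5 * (lo + hi))).astype(np.int8)
    flip_r = rng.random(n) < noise
    rarity = np.where(flip_r, 1 - yr, yr).astype(np.int8)

    # -- Bayes accuracy of the decline model (Monte Carlo) ----------------
    bayes = _bayes_accuracy(
        rng, values, names, informative, weights, intercept, noise,
        config.effect_model, n_draws=100_000,
    )

    # -- occupancy ---------------------------------------------------------
    site_ids = [f"cell{i:04d}" for i in range(config.n_sites)]
    site_group = np.array(
        [f"region_{i % config.n_site_groups}" for i in range(config.n_sites)],
        dtype=object,
    )
    pref_group = rng.integers(0, config.n_site_groups, size=n)
    # declining species occupy fewer cells and are more specialized
    occ_rate = np.clip(
        config.base_occupancy * (1.0 - 0.4 * decline), 0.02, 0.95
    )
    site_idx = np.array([int(s.split("_")[1]) for s in site_group])
    probs = np.empty((n, config.n_sites))
    for i in range(n):
        boost = (site_idx == pref_group[i]) * config.preference_strength * (
            1.0 + 0.5 * decline[i]
        )
        probs[i] = np.clip(occ_rate[i] * (1.0 + boost) - 0.2 * config.preference_strength * occ_rate[i], 0.0, 1.0)
    presence = (rng.random((n, config.n_sites)) < probs).astype(np.int8)
    occupancy = OccupancyTable(
        species_ids=species_ids,
        site_ids=site_ids,
        presence=presence,
        site_groups={"region": site_group},
        era="1950-1990",
    )

    # -- MCAR missingness per tier ----------------------------------------
    for j, spec in enumerate(specs):
        rate = (
            config.missing_rate.get(spec.tier, 0.0)
            if isinstance(config.missing_rate, dict)
            else float(config.missing_rate)
        )
        if rate > 0:
            values[rng.random(n) < rate, j] = MISSING

    table = SpeciesTable(
        species_ids=species_ids,
        kingdom=kingdom,
        group=leaf,
        values=values,
        specs=specs,
        rarity=rarity,
        decline=decline,
        group_parents=parents,
    )
    truth = GroundTruth(
        informative=informative,
        weights=weights,
        intercept=intercept,
        rule_description=rule_desc,
        bayes_accuracy=bayes,
        realized_prevalence=float(decline.mean()),
        rarity_informative=rarity_pool,
        realized_rarity_prevalence=float(rarity.mean()),
        label_noise={"default": noise.mean()},
    )
    return table, occupancy, truth


def _centered_col(values: np.ndarray, names: list[str], name: str) -> np.ndarray:
    col = values[:, names.index(name)].astype(float)
    sd = col.std()
    return (col - col.mean()) / (sd if sd > 0 else 1.0)


def _bayes_accuracy(
    rng: np.random.Generator,
    values: np.ndarray,
    names: list[str],
    informative: list[str],
    weights: dict[str, float],
    intercept: float,
    noise: np.ndarray,
    effect_model: str,
    n_draws: int,
) -> float:
    """Monte-Carlo Bayes-optimal accuracy of the planted decline model.

    Resamples species (with their noise rates) from the realized table;
    the optimal rule predicts the more probable post-noise class, so the
    attainable accuracy is E[max(q, 1 − q)] with q the post-noise
    positive-class probability.
    """
    n = values.shape[0]
    idx = rng.integers(0, n, size=n_draws)
    if not informative:
        q = _sigmoid(np.full(n_draws, intercept))
    else:
        z = np.zeros(n_draws)
        for a, w in weights.items():
            col = values[:, names.index(a)].astype(float)
            sd = col.std()
            z += w * ((col[idx] - col.mean()) / (sd if sd > 0 else 1.0))
        if effect_model == "rules":
            feats = []
            for a in informative:
                col = values[:, names.index(a)].astype(float)
                sd = col.std()
                feats.append(((col[idx] - col.mean()) / (sd if sd > 0 else 1.0)) > 0)
            acc = feats[0]
            for i in range(1, len(feats)):
                acc = (acc & feats[i]) if i % 2 else (acc | feats[i])
            z = np.where(acc, 12.0, -12.0)
        q = _sigmoid(z + intercept)
    q = q * (1 - noise[idx]) + (1 - q) * noise[idx]
    return float(np.mean(np.maximum(q, 1 - q)))


def mask_cells(
    table: SpeciesTable, rate: float, seed: int = 0
) -> tuple[SpeciesTable, np.ndarray]:
    """MCAR-mask an exact fraction of the observed cells.

    Returns the masked table and an (m, 2) array of (row, column) indices
    of the masked cells, for recovery scoring. The count is
    ``round(rate · n_observed)``, sampled without replacement from the
    originally observed cells.
    """
    if not (0.0 <= rate < 1.0):
        raise ValidationError("mask rate must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xA5]))
    obs = np.argwhere(table.values != MISSING)
    n_mask = int(round(rate * len(obs)))
    out = table.copy()
    if n_mask == 0:
        return out, np.empty((0, 2), dtype=int)
    pick = rng.choice(len(obs), size=n_mask, replace=False)
    cells = obs[pick]
    out.values[cells[:, 0], cells[:, 1]] = MISSING
    return out, cells
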