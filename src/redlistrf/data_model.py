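"""Core data containers for species-attribute tables.

The analysis operates on a species × attribute matrix of small categorical
codes. Attributes are categorical or ordinal with 2–10 levels, each tagged
with the lowest *availability tier* at which it could realistically be known
for an unassessed species (``poorly_known`` ⊂ ``well_known`` ⊂ ``evaluated``).
Species carry a taxonomic group label embedded in a parent-link hierarchy
(e.g. birds → vertebrates → animals) and optional binary rarity / decline
labels derived from ordered Red List categories.

Values are stored as integer codes ``0..k-1`` with ``-1`` marking a missing
cell; ordinals carry their order in the code, nominals do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

#: sentinel for a missing cell in the integer code matrix
MISSING: int = -1

KINDS = ("binary", "ordinal", "nominal")
TIERS = ("poorly_known", "well_known", "evaluated")
TIER_RANK = {t: i for i, t in enumerate(TIERS)}


class ValidationError(ValueError):
    """Raised when a table or metadata file violates its declared domain."""


@dataclass(frozen=True)
class AttributeSpec:
    """Metadata for one categorical/ordinal attribute.

    Parameters
    ----------
    name : str
        Attribute identifier (column name in the species table).
    kind : {"binary", "ordinal", "nominal"}
    n_categories : int
        Number of levels, 2–10.
    tier : {"poorly_known", "well_known", "evaluated"}
        Lowest availability tier at which the attribute is knowable.
    derivation : str
        Free-text provenance, e.g. ``raw``, ``phi``, ``specialization``,
        ``commonness``, ``dummy``.
    labels : tuple of str, optional
        Category labels as they appear in files; defaults to "0".."k-1".
    """

    name: str
    kind: str
    n_categories: int
    tier: str = "evaluated"
    derivation: str = "raw"
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"{self.name}: unknown kind {self.kind!r}")
        if self.tier not in TIERS:
            raise ValidationError(f"{self.name}: unknown tier {self.tier!r}")
        if not (2 <= self.n_categories <= 10):
            raise ValidationError(
                f"{self.name}: n_categories must be in [2, 10], got {self.n_categories}"
            )
        if self.kind == "binary" and self.n_categories != 2:
            raise ValidationError(f"{self.name}: binary attribute must have 2 categories")
        if self.labels is not None and len(self.labels) != self.n_categories:
            raise ValidationError(
                f"{self.name}: {len(self.labels)} labels for {self.n_categories} categories"
            )

    @property
    def category_labels(self) -> tuple[str, ...]:
        if self.labels is not None:
            return self.labels
        return tuple(str(i) for i in range(self.n_categories))


@dataclass
class SpeciesTable:
    """Species × attribute matrix with group hierarchy and binary labels.

    ``values`` holds integer category codes with :data:`MISSING` (-1) for
    missing cells. ``group_parents`` maps each group label to its parent
    (kingdoms have no entry or map to themselves).
    """

    species_ids: list[str]
    kingdom: np.ndarray
    group: np.ndarray
    values: np.ndarray
    specs: list[AttributeSpec]
    rarity: np.ndarray | None = None
    decline: np.ndarray | None = None
    group_parents: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.species_ids)
        if len(set(self.species_ids)) != n:
            dupes = pd.Series(self.species_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValidationError(f"duplicate species_id: {dupes}")
        self.values = np.asarray(self.values, dtype=np.int16)
        if self.values.shape != (n, len(self.specs)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{n} species × {len(self.specs)} attributes"
            )
        self.kingdom = np.asarray(self.kingdom, dtype=object)
        self.group = np.asarray(self.group, dtype=object)
        for axis in ("rarity", "decline"):
            lab = getattr(self, axis)
            if lab is not None:
                lab = np.asarray(lab, dtype=np.int8)
                if not np.isin(lab, (0, 1)).all():
                    raise ValidationError(f"{axis} labels must be binary 0/1")
                setattr(self, axis, lab)
        for j, spec in enumerate(self.specs):
            col = self.values[:, j]
            bad = (col != MISSING) & ((col < 0) | (col >= spec.n_categories))
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"species {self.species_ids[i]!r}: value {col[i]} outside the "
                    f"{spec.n_categories} categories of attribute {spec.name!r}"
                )

    # -- basic shape ------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_attributes(self) -> int:
        return len(self.specs)

    @property
    def attribute_names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def labels(self, axis: str) -> np.ndarray:
        lab = getattr(self, axis, None)
        if axis not in ("rarity", "decline") or lab is None:
            raise ValidationError(f"no labels for axis {axis!r}")
        return lab

    # -- hierarchy --------------------------------------------------------
    def ancestry(self, group_label: str) -> list[str]:
        """Group label plus all its ancestors (parent links, then kingdom)."""
        chain = [group_label]
        seen = {group_label}
        cur = group_label
        while cur in self.group_parents and self.group_parents[cur] not in seen:
            cur = self.group_parents[cur]
            chain.append(cur)
            seen.add(cur)
        return chain

    def group_mask(self, label: str) -> np.ndarray:
        """Boolean mask of species belonging to ``label`` or any descendant."""
        mask = np.zeros(self.n_species, dtype=bool)
        for i in range(self.n_species):
            if label == self.kingdom[i] or label in self.ancestry(str(self.group[i])):
                mask[i] = True
        return mask

    # -- subsetting -------------------------------------------------------
    def subset(
        self,
        rows: np.ndarray | None = None,
        attributes: list[str] | None = None,
    ) -> "SpeciesTable":
        """Row and/or column subset; labels and hierarchy carried along."""
        if rows is None:
            rows = np.ones(self.n_species, dtype=bool)
        rows = np.asarray(rows)
        if rows.dtype == bool:
            idx = np.flatnonzero(rows)
        else:
            idx = rows
        if attributes is None:
            cols = np.arange(self.n_attributes)
            specs = list(self.specs)
        else:
            pos = {s.name: j for j, s in enumerate(self.specs)}
            missing = [a for a in attributes if a not in pos]
            if missing:
                raise ValidationError(f"unknown attributes: {missing}")
            cols = np.array([pos[a] for a in attributes])
            specs = [self.specs[j] for j in cols]
        return SpeciesTable(
            species_ids=[self.species_ids[i] for i in idx],
            kingdom=self.kingdom[idx],
            group=self.group[idx],
            values=self.values[np.ix_(idx, cols)],
            specs=specs,
            rarity=None if self.rarity is None else self.rarity[idx],
            decline=None if self.decline is None else self.decline[idx],
            group_parents=dict(self.group_parents),
        )

    def copy(self) -> "SpeciesTable":
        return self.subset()

    def equals(self, other: "SpeciesTable") -> bool:
        return (
            self.species_ids == other.species_ids
            and (self.kingdom == other.kingdom).all()
            and (self.group == other.group).all()
            and np.array_equal(self.values, other.values)
            and self.specs == other.specs
            and _opt_eq(self.rarity, other.rarity)
            and _opt_eq(self.decline, other.decline)
            and self.group_parents == other.group_parents
        )


def _opt_eq(a: np.ndarray | None, b: np.ndarray | None) -> bool:
    if a is None or b is None:
        return a is None and b is None
    return np.array_equal(a, b)


# ---------------------------------------------------------------------------
# Red List category mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RedListMapping:
    """Ordered Red List categories and positive-label thresholds per axis.

    A species is *rare* when its rarity category is at or above the rarity
    threshold, and *declining* when its trend category is at or above the
    decline threshold. The mapping is monotone by construction.
    """

    rarity_categories: tuple[str, ...]
    rarity_threshold: str
    decline_categories: tuple[str, ...]
    decline_threshold: str

    def __post_init__(self) -> None:
        if self.rarity_threshold not in self.rarity_categories:
            raise ValidationError("rarity threshold not in category list")
        if self.decline_threshold not in self.decline_categories:
            raise ValidationError("decline threshold not in category list")

    @classmethod
    def from_yaml(cls, path) -> "RedListMapping":
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            rarity_categories=tuple(cfg["rarity"]["categories"]),
            rarity_threshold=cfg["rarity"]["threshold"],
            decline_categories=tuple(cfg["decline"]["categories"]),
            decline_threshold=cfg["decline"]["threshold"],
        )


def default_redlist_mapping() -> RedListMapping:
    """Default Dutch-style category orderings.

    The exact per-group category systems vary; only the two thresholds are
    fixed by the analysis definition ("rare" and higher count as rare,
    "moderately declining" and higher as declining). Other category names
    are configurable via :meth:`RedListMapping.from_yaml`.
    """
    return RedListMapping(
        rarity_categories=(
            "very common", "common", "fairly rare", "rare", "very rare", "extremely rare",
        ),
        rarity_threshold="rare",
        decline_categories=(
            "stable or increasing", "slightly declining", "moderately declining",
            "strongly declining", "very strongly declining",
        ),
        decline_threshold="moderately declining",
    )


def map_redlist(category: str, mapping: RedListMapping, axis: str) -> int:
    """Binary label: 1 iff ``category`` is at or above the axis threshold."""
    if axis == "rarity":
        cats, thr = mapping.rarity_categories, mapping.rarity_threshold
    elif axis == "decline":
        cats, thr = mapping.decline_categories, mapping.decline_threshold
    else:
        raise ValidationError(f"unknown axis {axis!r}")
    if category not in cats:
        raise ValidationError(f"unknown {axis} category {category!r}")
    return int(cats.index(category) >= cats.index(thr))


# ---------------------------------------------------------------------------
# Tier selection
# ---------------------------------------------------------------------------

def select_tier(
    table: SpeciesTable,
    tier: str,
    axis: str = "decline",
) -> SpeciesTable:
    """Column subset usable at an availability tier.

    Keeps attributes whose tier rank is at or below ``tier``. For the rarity
    axis the past-commonness attribute is always excluded (rarity is itself a
    function of present distribution, so commonness would leak the label).
    """
    if tier not in TIERS:
        raise ValidationError(f"unknown tier {tier!r}")
    if axis not in ("rarity", "decline"):
        raise ValidationError(f"unknown axis {axis!r}")
    keep = [
        s.name
        for s in table.specs
        if TIER_RANK[s.tier] <= TIER_RANK[tier]
        and not (axis == "rarity" and s.derivation == "commonness")
    ]
    return table.subset(attributes=keep)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_RESERVED = ("species_id", "kingdom", "group", "rarity", "decline")


def read_species_table(
    path,
    metadata_path,
    missing_token: str = "NA",
) -> tuple[SpeciesTable, list[AttributeSpec]]:
    """Read a species table (CSV/TSV) plus its attribute metadata (YAML).

    The table has one row per species with columns ``species_id``,
    ``kingdom``, ``group``, optional ``rarity``/``decline`` (0/1), then one
    column per attribute holding category labels; missing cells carry
    ``missing_token``. The metadata file declares each attribute
    (name/kind/n_categories/tier/derivation/categories) and the group
    hierarchy as parent links.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    with open(metadata_path, "r", encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    specs = [
        AttributeSpec(
            name=a["name"],
            kind=a["kind"],
            n_categories=int(a["n_categories"]),
            tier=a.get("tier", "evaluated"),
            derivation=a.get("derivation", "raw"),
            labels=tuple(str(x) for x in a["categories"]) if "categories" in a else None,
        )
        for a in meta["attributes"]
    ]
    spec_names = {s.name for s in specs}
    table_attrs = [c for c in df.columns if c not in _RESERVED]
    unknown = [c for c in table_attrs if c not in spec_names]
    if unknown:
        raise ValidationError(f"attributes in table but not metadata: {unknown}")
    absent = [s.name for s in specs if s.name not in table_attrs]
    if absent:
        raise ValidationError(f"attributes in metadata but not table: {absent}")
    for col in ("species_id", "kingdom", "group"):
        if col not in df.columns:
            raise ValidationError(f"table lacks required column {col!r}")

    n = len(df)
    values = np.full((n, len(specs)), MISSING, dtype=np.int16)
    for j, spec in enumerate(specs):
        lut = {lab: k for k, lab in enumerate(spec.category_labels)}
        raw = df[spec.name].to_numpy()
        for i, cell in enumerate(raw):
            if cell == missing_token or cell == "":
                continue
            if cell not in lut:
                raise ValidationError(
                    f"species {df['species_id'].iloc[i]!r}: unknown value {cell!r} "
                    f"for attribute {spec.name!r}"
                )
            values[i, j] = lut[cell]

    def _labels(col: str) -> np.ndarray | None:
        if col not in df.columns:
            return None
        return df[col].astype(int).to_numpy()

    table = SpeciesTable(
        species_ids=df["species_id"].tolist(),
        kingdom=df["kingdom"].to_numpy(dtype=object),
        group=df["group"].to_numpy(dtype=object),
        values=values,
        specs=specs,
        rarity=_labels("rarity"),
        decline=_labels("decline"),
        group_parents=dict(meta.get("group_parents", {})),
    )
    return table, specs


def write_species_table(
    table: SpeciesTable,
    path,
    metadata_path,
    missing_token: str = "NA",
) -> None:
    """Inverse of :func:`read_species_table` (exact round trip)."""
    cols: dict[str, object] = {
        "species_id": table.species_ids,
        "kingdom": table.kingdom,
        "group": table.group,
    }
    if table.rarity is not None:
        cols["rarity"] = table.rarity
    if table.decline is not None:
        cols["decline"] = table.decline
    for j, spec in enumerate(table.specs):
        labs = spec.category_labels
        col = [
            missing_token if v == MISSING else labs[v] for v in table.values[:, j]
        ]
        cols[spec.name] = col
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)

    attrs = []
    for s in table.specs:
        entry = {
            "name": s.name,
            "kind": s.kind,
            "n_categories": s.n_categories,
            "tier": s.tier,
            "derivation": s.derivation,
        }
        if s.labels is not None:  # default "0".."k-1" labels stay implicit
            entry["categories"] = list(s.labels)
        attrs.append(entry)
    meta = {"group_parents": dict(table.group_parents), "attributes": attrs}
    with open(metadata_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
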