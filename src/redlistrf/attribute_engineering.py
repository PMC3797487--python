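"""Derive categorical model attributes from raw traits and occupancy data.

Distribution data enter the analysis through three derived quantities:

* the **group-equalized phi coefficient** of a species' presence against each
  site group of a grouping scheme (land-use category, physio-geographical
  region): the classical 2×2 phi between presence and group membership after
  every group is reweighted to equal size,
* **specialization**, the Euclidean norm of the phi profile across the
  groups of a scheme, and
* **commonness**, the logit of the fraction of group-occupied grid cells the
  species occupied.

Scale-valued quantities (including the above) are discretized into
five-level ordinals over equal-width bins so that every model attribute is
categorical; nominal traits that are inapplicable to some species are
expanded into per-level dummies with all-zero rows for the inapplicable
species. Finally, near-constant attributes (> 99 % of species in one
category) and attributes with > 25 % missing values are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import MISSING, AttributeSpec, SpeciesTable, ValidationError

#: marker for "this trait is not applicable to this species" (distinct from missing)
NOT_APPLICABLE = "not_applicable"


# ---------------------------------------------------------------------------
# Occupancy container
# ---------------------------------------------------------------------------

@dataclass
class OccupancyTable:
    """Species × site presence matrix with one or more site-group schemes.

    ``site_groups`` maps a scheme name (e.g. ``"land_use"`` or ``"region"``)
    to a per-site group label array. Presence is binary.
    """

    species_ids: list[str]
    site_ids: list[str]
    presence: np.ndarray
    site_groups: dict[str, np.ndarray]
    era: str = ""

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence)
        if not np.isin(self.presence, (0, 1)).all():
            raise ValidationError("presence matrix must be binary")
        self.presence = self.presence.astype(np.int8)
        if self.presence.shape != (len(self.species_ids), len(self.site_ids)):
            raise ValidationError("presence shape does not match species × sites")
        for scheme, labels in self.site_groups.items():
            labels = np.asarray(labels, dtype=object)
            if len(labels) != len(self.site_ids):
                raise ValidationError(f"scheme {scheme!r}: one label per site required")
            if len(np.unique(labels)) < 2:
                raise ValidationError(f"scheme {scheme!r}: at least 2 site groups required")
            self.site_groups[scheme] = labels

    @classmethod
    def read(cls, presence_path, sites_path, era: str = "") -> "OccupancyTable":
        """Load a 0/1 CSV (rows = species) plus a site metadata CSV.

        The site file has a ``site_id`` column and one column per grouping
        scheme.
        """
        pres = pd.read_csv(presence_path, index_col=0)
        sites = pd.read_csv(sites_path, dtype=str)
        if list(pres.columns) != sites["site_id"].tolist():
            raise ValidationError("site order differs between presence and site files")
        schemes = {
            c: sites[c].to_numpy(dtype=object) for c in sites.columns if c != "site_id"
        }
        return cls(
            species_ids=[str(i) for i in pres.index],
            site_ids=list(pres.columns),
            presence=pres.to_numpy(),
            site_groups=schemes,
            era=era,
        )


@dataclass(frozen=True)
class PhiProfile:
    """Per-group phi coefficients of one species under one scheme."""

    groups: tuple[str, ...]
    phi: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi", np.asarray(self.phi, dtype=float))
        if np.any(np.abs(self.phi) > 1 + 1e-12):
            raise ValidationError("phi coefficients must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# Preference / specialization / commonness
# ---------------------------------------------------------------------------

def phi_coefficient(presence_row: np.ndarray, site_groups: np.ndarray) -> PhiProfile:
    """Group-equalized phi of a presence row against each site group.

    With ``f_k`` the within-group occupied fraction and ``f̄`` their mean
    over the K groups,

        φ_k = (f_k − f̄) / sqrt((K − 1) · f̄ · (1 − f̄)).

    This equals the classical 2×2 phi coefficient (presence ×
    membership-in-group-k) computed after every group is reweighted to equal
    size. A species present everywhere or nowhere (f̄ ∈ {0, 1}) carries no
    preference signal and gets φ_k = 0 throughout.
    """
    presence_row = np.asarray(presence_row)
    if not np.isin(presence_row, (0, 1)).all():
        raise ValidationError("presence row must be binary")
    site_groups = np.asarray(site_groups, dtype=object)
    groups = sorted(set(site_groups.tolist()))
    if len(groups) < 2:
        raise ValidationError("at least 2 site groups required")
    f = np.empty(len(groups))
    for k, g in enumerate(groups):
        mask = site_groups == g
        n_k = int(mask.sum())
        if n_k == 0:
            raise ValidationError(f"empty site group {g!r}")
        f[k] = presence_row[mask].mean()
    fbar = f.mean()
    if fbar in (0.0, 1.0):
        return PhiProfile(groups=tuple(groups), phi=np.zeros(len(groups)))
    K = len(groups)
    phi = (f - fbar) / math.sqrt((K - 1) * fbar * (1.0 - fbar))
    return PhiProfile(groups=tuple(groups), phi=phi)


def specialization(profile: PhiProfile) -> float:
    """Euclidean norm of the phi profile: S = sqrt(Σ_k φ_k²)."""
    return float(np.sqrt(np.sum(profile.phi ** 2)))


def commonness(occupied_cells: int, group_cells: int) -> float:
    """Logit of the occupied fraction of group-observed grid cells.

    Uses the Haldane correction p′ = (a + 0.5)/(N + 1) so that species
    observed in none or all cells map to finite values.
    """
    if group_cells <= 0:
        raise ValidationError("group_cells must be positive")
    if not (0 <= occupied_cells <= group_cells):
        raise ValidationError("occupied_cells outside [0, group_cells]")
    p = (occupied_cells + 0.5) / (group_cells + 1.0)
    return math.log(p / (1.0 - p))


def phi_attribute_frame(occ: OccupancyTable, scheme: str) -> pd.DataFrame:
    """Per-species phi coefficients and specialization for one scheme.

    Convenience wrapper over :func:`phi_coefficient` /
    :func:`specialization`; columns are ``phi_<scheme>_<group>`` plus
    ``specialization_<scheme>``, indexed by species id.
    """
    labels = occ.site_groups[scheme]
    rows = {}
    for i, sp in enumerate(occ.species_ids):
        prof = phi_coefficient(occ.presence[i], labels)
        rows[sp] = list(prof.phi) + [specialization(prof)]
    groups = sorted(set(labels.tolist()))
    cols = [f"phi_{scheme}_{g}" for g in groups] + [f"specialization_{scheme}"]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


# ---------------------------------------------------------------------------
# Discretization and dummy expansion
# ---------------------------------------------------------------------------

def bin_ordinal(values: np.ndarray, use_log: bool = False) -> np.ndarray:
    """Discretize a scale variable into a five-level ordinal (codes 0–4).

    Bins are equal-width over the observed [min, max] of the non-missing
    (optionally log-transformed) values. Values exactly on an interior edge
    fall in the lower bin; the global maximum falls in the top bin. Missing
    (NaN) entries stay missing.
    """
    v = np.asarray(values, dtype=float).copy()
    obs = ~np.isnan(v)
    x = v[obs]
    if use_log:
        if np.any(x <= 0):
            raise ValidationError("log transform requires strictly positive values")
        x = np.log(x)
    if len(np.unique(x)) < 2:
        raise ValidationError("constant (or empty) vector cannot be binned")
    edges = np.linspace(x.min(), x.max(), 6)
    codes = np.searchsorted(edges[1:-1], x, side="left").astype(float)
    out = np.full(v.shape, np.nan)
    out[obs] = codes
    return out


def dummy_expand(values, spec: AttributeSpec) -> pd.DataFrame:
    """Expand a nominal trait with inapplicable entries into per-level dummies.

    Input values are level labels, :data:`NOT_APPLICABLE` for species the
    trait has no meaning for (→ 0 in every dummy), or NaN for missing
    (→ NaN in every dummy). Returns one 0/1 column per declared level,
    named ``<attr>=<level>``.
    """
    s = pd.Series(values)
    levels = spec.category_labels
    known = set(levels) | {NOT_APPLICABLE}
    bad = s.dropna()[~s.dropna().isin(known)]
    if len(bad):
        raise ValidationError(f"{spec.name}: unknown level(s) {sorted(set(bad))}")
    out = {}
    for lev in levels:
        col = np.where(s.isna(), np.nan, (s == lev).astype(float))
        out[f"{spec.name}={lev}"] = col
    return pd.DataFrame(out, index=s.index)


# ---------------------------------------------------------------------------
# Attribute filtering
# ---------------------------------------------------------------------------

def filter_attributes(
    table: SpeciesTable,
    max_dominant_share: float = 0.99,
    max_missing_share: float = 0.25,
) -> tuple[SpeciesTable, pd.DataFrame]:
    """Drop uninformative and poorly observed attributes.

    An attribute is dropped when *strictly* more than ``max_dominant_share``
    of its non-missing values fall in one category (uninformative), or when
    strictly more than ``max_missing_share`` of its values are missing
    (imputation would be unreliable). Shares are computed on the species
    subset in ``table``. Returns the filtered table and a removal report
    with columns ``attribute``, ``rule``, ``fraction``.
    """
    report = []
    keep = []
    n = table.n_species
    for j, spec in enumerate(table.specs):
        col = table.values[:, j]
        obs = col != MISSING
        missing_share = 1.0 - obs.sum() / n
        if missing_share > max_missing_share:
            report.append((spec.name, "missing", missing_share))
            continue
        counts = np.bincount(col[obs], minlength=spec.n_categories)
        dominant = counts.max() / counts.sum() if counts.sum() else 1.0
        if dominant > max_dominant_share:
            report.append((spec.name, "dominant_category", dominant))
            continue
        keep.append(spec.name)
    if not keep:
        raise ValidationError("all attributes removed by filtering")
    report_df = pd.DataFrame(report, columns=["attribute", "rule", "fraction"])
    return table.subset(attributes=keep), report_df
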