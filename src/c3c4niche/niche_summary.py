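"""Species- and lineage-level niche summaries.

The unit of analysis is the species median: per species and per variable, the
median over retained occurrences, chosen over the mean for robustness to
misidentified or badly georeferenced points.  Lineage-level values are the
arithmetic mean of member-species medians ("mean of medians"), computed
separately for each photosynthetic type within a comparison group.

Also provides the descriptive range table (per-lineage min-max of geography,
climate and soils over pooled C3-C4 members) and a Whittaker-style biome
classification of (MAT, MAP) points from a packaged synthetic polygon set.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .env_extraction import META_COLUMNS

logger = logging.getLogger(__name__)

PHOTOSYNTHETIC_TYPES = ("C3", "C3-C4", "C4")

RANGE_VARIABLES = (
    "latitude", "altitude", "MAT", "MAP",
    "organic_carbon", "TEB", "CEC", "pH",
)


@dataclass
class SpeciesNiche:
    """Per-variable occurrence medians for one taxon."""

    taxon: str
    medians: dict[str, float]
    counts: dict[str, int]


@dataclass
class ComparisonGroup:
    """A lineage with its species partitioned by photosynthetic type."""

    lineage: str
    members: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        for t in PHOTOSYNTHETIC_TYPES:
            self.members.setdefault(t, [])
        seen: set[str] = set()
        for t in PHOTOSYNTHETIC_TYPES:
            dup = seen & set(self.members[t])
            if dup:
                raise ValueError(f"{self.lineage}: species in two type sets: {sorted(dup)}")
            seen |= set(self.members[t])
        if not self.members["C3-C4"]:
            raise ValueError(f"{self.lineage}: comparison group needs C3-C4 members")

    @property
    def has_C4_sister(self) -> bool:
        return bool(self.members["C4"])

    @property
    def has_C3_sister(self) -> bool:
        return bool(self.members["C3"])


@dataclass
class GroupNiche:
    """Mean of member-species medians for one lineage x type."""

    lineage: str
    type: str
    values: dict[str, float]


def _value_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c not in META_COLUMNS]


def species_median(matrix: pd.DataFrame, taxon: str) -> SpeciesNiche:
    """Median of non-missing occurrence values per variable for one taxon.

    Variables with zero non-missing occurrences are absent from the result.
    """
    rows = matrix[matrix["taxon"] == taxon]
    if rows.empty:
        raise KeyError(f"taxon {taxon!r} has no retained occurrences")
    if len(rows) == 1:
        logger.warning("taxon %s has a single occurrence; medians equal that row", taxon)
    medians, counts = {}, {}
    for var in _value_columns(matrix):
        vals = rows[var].dropna()
        if len(vals):
            medians[var] = float(vals.median())
            counts[var] = int(len(vals))
    return SpeciesNiche(taxon=taxon, medians=medians, counts=counts)


def all_species_medians(matrix: pd.DataFrame) -> dict[str, SpeciesNiche]:
    return {t: species_median(matrix, t) for t in sorted(matrix["taxon"].unique())}


def group_mean_of_medians(
    niches: dict[str, SpeciesNiche], group: ComparisonGroup, type: str
) -> GroupNiche | None:
    """Mean of member medians per variable; species lacking a variable are skipped.

    Returns None for an empty C4 set (lineage without a C4 sister); an empty
    set of any other type is an error.
    """
    members = group.members[type]
    if not members:
        if type == "C4":
            return None
        raise ValueError(f"{group.lineage}: no {type} members")
    missing = [m for m in members if m not in niches]
    if missing:
        raise KeyError(f"{group.lineage}: no niche for species {missing}")
    values: dict[str, float] = {}
    variables = sorted({v for m in members for v in niches[m].medians})
    for var in variables:
        vals = [niches[m].medians[var] for m in members if var in niches[m].medians]
        values[var] = float(np.mean(vals))
    return GroupNiche(lineage=group.lineage, type=type, values=values)


def group_niche_table(
    niches: dict[str, SpeciesNiche], groups: list[ComparisonGroup]
) -> pd.DataFrame:
    """Long-format table of lineage x type mean-of-medians values."""
    rows = []
    for g in groups:
        for t in PHOTOSYNTHETIC_TYPES:
            if not g.members[t]:
                continue
            gn = group_mean_of_medians(niches, g, t)
            for var, val in sorted(gn.values.items()):
                rows.append(
                    {"lineage": g.lineage, "type": t, "variable": var, "value": val}
                )
    return pd.DataFrame(rows, columns=["lineage", "type", "variable", "value"])


def range_table(matrix: pd.DataFrame, groups: list[ComparisonGroup]) -> pd.DataFrame:
    """Per-lineage occurrence counts and min-max ranges over pooled C3-C4 members."""
    rows = []
    variables = [v for v in RANGE_VARIABLES if v in matrix.columns]
    for g in sorted(groups, key=lambda g: g.lineage):
        sub = matrix[matrix["taxon"].isin(g.members["C3-C4"])]
        if sub.empty:
            warnings.warn(f"lineage {g.lineage} has no retained C3-C4 occurrences; omitted")
            continue
        row = {"lineage": g.lineage, "n": int(len(sub))}
        for var in variables:
            vals = sub[var].dropna()
            row[f"{var}_min"] = float(vals.min()) if len(vals) else np.nan
            row[f"{var}_max"] = float(vals.max()) if len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Biome classification (descriptive only)

@lru_cache(maxsize=1)
def _biome_polygons() -> list[tuple[str, Polygon]]:
    """Synthetic Whittaker-diagram polygon set packaged with the library.

    The vertex file is a hand-digitized approximation of the classic
    temperature-precipitation diagram (see its own description field), kept
    in a fixed order so that boundary points resolve deterministically.
    """
    ref = resources.files("c3c4niche.data").joinpath("biome_polygons_synthetic.json")
    payload = json.loads(ref.read_text())
    return [(name, Polygon(verts)) for name, verts in payload["polygons"].items()]


BIOME_LABELS = ("TrRF", "TeRF", "TF", "TSF", "WGS", "S", "D", "Ta", "Tu")


def classify_biome(mat: float, map_mm: float) -> str:
    """Label of the (MAT, MAP) biome polygon; outside points map to the nearest.

    Total over finite inputs: every point receives exactly one label.
    """
    if not (np.isfinite(mat) and np.isfinite(map_mm)):
        raise ValueError("classify_biome requires finite MAT and MAP")
    pt = Point(mat, map_mm)
    best, best_dist = None, np.inf
    for name, poly in _biome_polygons():
        if poly.covers(pt):
            return name
        d = poly.distance(pt)
        if d < best_dist:
            best, best_dist = name, d
    return best


# ---------------------------------------------------------------------------
# Group-membership CSV interface

def read_membership(path) -> list[ComparisonGroup]:
    """Read `lineage,species,photosynthetic_type` CSV into comparison groups."""
    df = pd.read_csv(path)
    required = {"lineage", "species", "photosynthetic_type"}
    if missing := required - set(df.columns):
        raise ValueError(f"membership CSV missing columns: {sorted(missing)}")
    bad = set(df["photosynthetic_type"]) - set(PHOTOSYNTHETIC_TYPES)
    if bad:
        raise ValueError(f"unknown photosynthetic types: {sorted(bad)}")
    groups = []
    for lineage, sub in df.groupby("lineage", sort=True):
        members = {
            t: sub.loc[sub["photosynthetic_type"] == t, "species"].tolist()
            for t in PHOTOSYNTHETIC_TYPES
        }
        groups.append(ComparisonGroup(lineage=str(lineage), members=members))
    return groups


def write_membership(groups: list[ComparisonGroup], path) -> None:
    rows = [
        {"lineage": g.lineage, "species": s, "photosynthetic_type": t}
        for g in groups
        for t in PHOTOSYNTHETIC_TYPES
        for s in g.members[t]
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
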