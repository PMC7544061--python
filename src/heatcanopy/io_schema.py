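"""Domain types and file I/O for the heat-vulnerability planting tool.

Everything the pipeline reads or writes passes through this module: the
census-tract variable table feeding the heat vulnerability index (HVI),
block-group land cover in square feet, tract-level mean summer land surface
temperature (LST), the approved tree-species table, and tract boundary
geometries.  All geographic identifiers are fixed-width GEOID strings
(11 characters for tracts, 12 for block groups) and are never coerced to
integers, so leading zeros survive every round trip.  Percentages live on
the 0-100 scale throughout.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger("heatcanopy")

TRACT_GEOID_LEN = 11
BLOCKGROUP_GEOID_LEN = 12


class ValidationError(ValueError):
    """Input data violates a documented invariant."""


class SchemaError(ValidationError):
    """Table columns do not match the configured variable schema."""


class JoinError(ValueError):
    """Two per-tract inputs do not cover the same tract set."""


# ---------------------------------------------------------------------------
# Variable schema
# ---------------------------------------------------------------------------

class Direction(str, Enum):
    """Whether larger values of a variable indicate more heat vulnerability.

    Rotated components have arbitrary sign; the schema's direction flags fix
    the orientation so that high component scores mean high vulnerability.
    Open undeveloped land is protective (cooler, plantable), hence decreasing.
    """

    INCREASING = "vulnerability_increasing"
    DECREASING = "vulnerability_decreasing"


@dataclass(frozen=True)
class VariableSchema:
    """Ordered list of (variable name, vulnerability direction)."""

    entries: tuple[tuple[str, Direction], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(names) < 2:
            raise ValidationError("schema needs at least 2 variables")
        if len(set(names)) != len(names):
            raise ValidationError("schema variable names must be unique")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    @property
    def increasing(self) -> list[str]:
        return [n for n, d in self.entries if d is Direction.INCREASING]

    def direction(self, name: str) -> Direction:
        for n, d in self.entries:
            if n == name:
                return d
        raise KeyError(name)

    @staticmethod
    def from_mapping(pairs: Mapping[str, str] | Sequence[tuple[str, str]]) -> "VariableSchema":
        items = pairs.items() if isinstance(pairs, Mapping) else pairs
        return VariableSchema(tuple((n, Direction(d)) for n, d in items))


#: Variables on the 0-100 percentage scale in the default schema.
PERCENTAGE_VARIABLES = (
    "pct_hispanic",
    "pct_black",
    "pct_foreign_born",
    "pct_limited_english",
    "pct_below_poverty",
    "pct_over65",
    "pct_over65_alone",
    "pct_disability_18_64",
    "pct_unemployed_18_64",
    "pct_housing_pre1980",
    "pct_high_intensity_developed",
    "pct_open_undeveloped",
)


def default_schema() -> VariableSchema:
    """The 13-variable Boston heat-vulnerability schema.

    Nine sociodemographic percentages, housing age and density, and two
    land-development percentages.  All are vulnerability-increasing except
    open undeveloped land.
    """
    inc = Direction.INCREASING
    return VariableSchema((
        ("pct_hispanic", inc),
        ("pct_black", inc),
        ("pct_foreign_born", inc),
        ("pct_limited_english", inc),
        ("pct_below_poverty", inc),
        ("pct_over65", inc),
        ("pct_over65_alone", inc),
        ("pct_disability_18_64", inc),
        ("pct_unemployed_18_64", inc),
        ("pct_housing_pre1980", inc),
        ("housing_density", inc),
        ("pct_high_intensity_developed", inc),
        ("pct_open_undeveloped", Direction.DECREASING),
    ))


# ---------------------------------------------------------------------------
# Tract variable table
# ---------------------------------------------------------------------------

@dataclass
class TractVariableTable:
    """Per-tract raw values for the schema variables, keyed by tract GEOID.

    ``data`` is indexed by the 11-character tract GEOID (string dtype) with
    one float column per schema variable, in schema order.
    """

    data: pd.DataFrame
    schema: VariableSchema

    def __post_init__(self) -> None:
        self.data = validate_tract_frame(self.data, self.schema)

    @property
    def tract_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)


def _check_geoid(value: object, length: int, what: str) -> str:
    s = str(value)
    if len(s) != length or not s.isdigit():
        raise ValidationError(
            f"{what} GEOID {s!r} must be a {length}-character digit string"
        )
    return s


def validate_tract_frame(df: pd.DataFrame, schema: VariableSchema) -> pd.DataFrame:
    """Validate and normalize a tract-variable frame against the schema.

    Column order is normalized to schema order; the index becomes the tract
    GEOID string.  Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` for duplicate tracts, missing values,
    out-of-range percentages or negative densities.
    """
    df = df.copy()
    if df.index.name != "tract_id":
        if "tract_id" not in df.columns:
            raise SchemaError("missing required column 'tract_id'")
        df["tract_id"] = [_check_geoid(g, TRACT_GEOID_LEN, "tract") for g in df["tract_id"]]
        df = df.set_index("tract_id")
    else:
        df.index = [_check_geoid(g, TRACT_GEOID_LEN, "tract") for g in df.index]
        df.index.name = "tract_id"
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()])
        raise ValidationError(f"duplicate tract_id values: {dups}")

    missing = [n for n in schema.names if n not in df.columns]
    if missing:
        raise SchemaError(f"missing schema column(s): {', '.join(missing)}")
    df = df[schema.names]

    for col in schema.names:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            rows = list(df.index[bad.isna() & df[col].notna()])
            raise ValidationError(
                f"non-numeric value in column {col!r} (tract(s) {rows})"
            ) from exc
        if df[col].isna().any():
            rows = list(df.index[df[col].isna()])
            raise ValidationError(f"missing value in column {col!r} for tract(s) {rows}")
        if col in PERCENTAGE_VARIABLES:
            bad = df.index[(df[col] < 0) | (df[col] > 100)]
            if len(bad):
                raise ValidationError(
                    f"column {col!r} outside range [0,100] for tract(s) {list(bad)}"
                )
        elif (df[col] < 0).any():
            bad = list(df.index[df[col] < 0])
            raise ValidationError(f"column {col!r} negative for tract(s) {bad}")
    return df


def read_tract_table(
    path: str | Path,
    schema: VariableSchema | None = None,
    *,
    impute_median: bool = False,
) -> TractVariableTable:
    """Read and validate the census-tract variable CSV.

    A tract with any missing schema variable is rejected unless
    ``impute_median`` is set, in which case the cohort median fills the gap
    and the imputation is logged per variable.
    """
    schema = schema or default_schema()
    df = pd.read_csv(path, dtype={"tract_id": str})
    if impute_median:
        for col in schema.names:
            if col in df.columns and df[col].isna().any():
                med = df[col].median()
                n = int(df[col].isna().sum())
                logger.info("imputing %d missing value(s) in %s with median %.4g", n, col, med)
                df[col] = df[col].fillna(med)
    return TractVariableTable(df, schema)


def write_tract_table(table: TractVariableTable, path: str | Path) -> None:
    table.data.to_csv(path, index=True)


# ---------------------------------------------------------------------------
# Land cover
# ---------------------------------------------------------------------------

class LandCoverClass(str, Enum):
    """Mutually exclusive land-cover classes of the high-resolution dataset."""

    TREE_CANOPY = "tree_canopy"
    VEGETATION = "vegetation_grass_shrub"
    IMPERVIOUS = "impervious"
    BUILDING = "building"
    OTHER = "other"


LAND_COVER_CLASSES = tuple(c.value for c in LandCoverClass)


@dataclass(frozen=True)
class LandCoverRecord:
    """Square footage of one cover class within one census block group."""

    block_group_id: str
    cover_class: LandCoverClass
    area_sqft: float

    def __post_init__(self) -> None:
        _check_geoid(self.block_group_id, BLOCKGROUP_GEOID_LEN, "block group")
        if not isinstance(self.cover_class, LandCoverClass):
            object.__setattr__(self, "cover_class", LandCoverClass(self.cover_class))
        if not math.isfinite(self.area_sqft) or self.area_sqft < 0:
            raise ValidationError(
                f"area_sqft must be a finite non-negative number, got {self.area_sqft!r} "
                f"for block group {self.block_group_id}"
            )

    @property
    def tract_id(self) -> str:
        """Parent tract GEOID: the first 11 characters of the block-group GEOID."""
        return self.block_group_id[:TRACT_GEOID_LEN]


def read_landcover(path: str | Path) -> list[LandCoverRecord]:
    """Read the block-group land-cover CSV (block_group_id, class, area_sqft)."""
    df = pd.read_csv(path, dtype={"block_group_id": str})
    for col in ("block_group_id", "class", "area_sqft"):
        if col not in df.columns:
            raise SchemaError(f"land-cover table missing column {col!r}")
    records: list[LandCoverRecord] = []
    seen: set[tuple[str, str]] = set()
    for bg_id, cls, area in zip(df["block_group_id"], df["class"], df["area_sqft"]):
        cls = str(cls)
        if cls not in LAND_COVER_CLASSES:
            raise ValidationError(
                f"unknown land-cover class {cls!r}; accepted classes: "
                f"{', '.join(LAND_COVER_CLASSES)}"
            )
        key = (str(bg_id), cls)
        if key in seen:
            raise ValidationError(f"duplicate (block_group_id, class) pair {key}")
        seen.add(key)
        records.append(LandCoverRecord(str(bg_id), LandCoverClass(cls), float(area)))
    return records


def write_landcover(records: Iterable[LandCoverRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"block_group_id": r.block_group_id, "class": r.cover_class.value,
             "area_sqft": r.area_sqft}
            for r in records
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Land surface temperature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LstRecord:
    """Mean summer mid-morning land surface temperature for one tract, in deg C."""

    tract_id: str
    mean_summer_lst: float

    def __post_init__(self) -> None:
        _check_geoid(self.tract_id, TRACT_GEOID_LEN, "tract")
        if not math.isfinite(self.mean_summer_lst):
            raise ValidationError(f"non-finite LST for tract {self.tract_id}")


def read_lst_table(path: str | Path) -> list[LstRecord]:
    df = pd.read_csv(path, dtype={"tract_id": str})
    for col in ("tract_id", "mean_summer_lst"):
        if col not in df.columns:
            raise SchemaError(f"LST table missing column {col!r}")
    if df["tract_id"].duplicated().any():
        dups = sorted(df["tract_id"][df["tract_id"].duplicated()])
        raise ValidationError(f"duplicate tract_id in LST table: {dups}")
    return [
        LstRecord(str(r.tract_id), float(r.mean_summer_lst))
        for r in df.itertuples(index=False)
    ]


def write_lst_table(records: Iterable[LstRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"tract_id": r.tract_id, "mean_summer_lst": r.mean_summer_lst} for r in records]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Species table
# ---------------------------------------------------------------------------

class LightRequirement(str, Enum):
    FULL_SUN = "full_sun"
    PARTIAL = "partial"
    SHADE_TOLERANT = "shade_tolerant"


class Allergenicity(str, Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


class GrowthRate(str, Enum):
    SLOW = "slow"
    MEDIUM = "medium"
    FAST = "fast"


class SiteType(str, Enum):
    STREET = "street"
    PARK_YARD = "park_yard"


ALLERGENICITY_ORDER = {Allergenicity.LOW: 0, Allergenicity.MEDIUM: 1, Allergenicity.HIGH: 2}
GROWTH_ORDER = {GrowthRate.SLOW: 0, GrowthRate.MEDIUM: 1, GrowthRate.FAST: 2}
#: Light-tolerance ordering: a shade-tolerant tree thrives in any light, a
#: partial-shade tree also handles full sun, a full-sun tree needs full sun.
LIGHT_TOLERANCE_ORDER = {
    LightRequirement.FULL_SUN: 0,
    LightRequirement.PARTIAL: 1,
    LightRequirement.SHADE_TOLERANT: 2,
}


@dataclass
class SpeciesRecord:
    """One approved tree species with its filterable site attributes."""

    species_name: str
    common_name: str
    canopy_spread_ft: float
    height_ft: float
    light_requirement: LightRequirement
    breakage_resistant: bool
    site_type: frozenset[SiteType]
    allergenicity: Allergenicity
    growth_rate: GrowthRate
    transpiration_rate: float
    leaf_area: float
    high_heat_reduction: bool | None = None

    def __post_init__(self) -> None:
        self.light_requirement = LightRequirement(self.light_requirement)
        self.allergenicity = Allergenicity(self.allergenicity)
        self.growth_rate = GrowthRate(self.growth_rate)
        self.site_type = frozenset(SiteType(s) for s in self.site_type)
        if not self.site_type:
            raise ValidationError(f"{self.species_name}: site_type must be non-empty")
        for attr in ("canopy_spread_ft", "height_ft", "transpiration_rate", "leaf_area"):
            v = getattr(self, attr)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValidationError(f"{self.species_name}: {attr} must be positive, got {v!r}")


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValidationError(f"cannot parse boolean from {value!r}")


def read_species_table(path: str | Path) -> list[SpeciesRecord]:
    """Read the tree-species attribute CSV.

    The ``high_heat_reduction`` column is optional on read; the species
    selector recomputes it from transpiration rate and leaf area.
    ``site_type`` holds one or more classes joined by ``;``.
    """
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("species table %s is empty", path)
        return []
    if df["species_name"].duplicated().any():
        dups = sorted(df["species_name"][df["species_name"].duplicated()])
        raise ValidationError(f"duplicate species_name values: {dups}")
    records = []
    for row in df.itertuples(index=False):
        hhr = getattr(row, "high_heat_reduction", None)
        records.append(
            SpeciesRecord(
                species_name=str(row.species_name),
                common_name=str(row.common_name),
                canopy_spread_ft=float(row.canopy_spread_ft),
                height_ft=float(row.height_ft),
                light_requirement=LightRequirement(row.light_requirement),
                breakage_resistant=_parse_bool(row.breakage_resistant),
                site_type=frozenset(
                    SiteType(s) for s in str(row.site_type).split(";") if s
                ),
                allergenicity=Allergenicity(row.allergenicity),
                growth_rate=GrowthRate(row.growth_rate),
                transpiration_rate=float(row.transpiration_rate),
                leaf_area=float(row.leaf_area),
                high_heat_reduction=None if hhr is None or pd.isna(hhr) else _parse_bool(hhr),
            )
        )
    return records


def write_species_table(records: Iterable[SpeciesRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "species_name": r.species_name,
                "common_name": r.common_name,
                "canopy_spread_ft": r.canopy_spread_ft,
                "height_ft": r.height_ft,
                "light_requirement": r.light_requirement.value,
                "breakage_resistant": r.breakage_resistant,
                "site_type": ";".join(sorted(s.value for s in r.site_type)),
                "allergenicity": r.allergenicity.value,
                "growth_rate": r.growth_rate.value,
                "transpiration_rate": r.transpiration_rate,
                "leaf_area": r.leaf_area,
                "high_heat_reduction": r.high_heat_reduction,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def packaged_species_path() -> Path:
    """Path of the packaged 34-row synthetic species fixture."""
    return Path(__file__).parent / "data" / "species_synthetic.csv"


# ---------------------------------------------------------------------------
# Tract geometries and GeoJSON output
# ---------------------------------------------------------------------------

@dataclass
class TractGeometry:
    """Tract boundary polygon in WGS84 longitude/latitude plus its area."""

    tract_id: str
    geometry: BaseGeometry
    area_sqft: float

    def __post_init__(self) -> None:
        _check_geoid(self.tract_id, TRACT_GEOID_LEN, "tract")
        if not self.geometry.is_valid:
            raise ValidationError(f"invalid geometry for tract {self.tract_id}")
        if self.area_sqft <= 0:
            raise ValidationError(f"non-positive area for tract {self.tract_id}")


def read_tract_geojson(path: str | Path) -> list[TractGeometry]:
    with open(path, encoding="utf-8") as fh:
        fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise ValidationError("geometry file is not a GeoJSON FeatureCollection")
    geoms = []
    for feat in fc["features"]:
        props = feat.get("properties", {})
        geoms.append(
            TractGeometry(
                tract_id=str(props["tract_id"]),
                geometry=shapely_shape(feat["geometry"]),
                area_sqft=float(props["area_sqft"]),
            )
        )
    ids = [g.tract_id for g in geoms]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate tract_id in geometry file")
    return geoms


def write_tract_geojson(geometries: Sequence[TractGeometry], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": shapely_mapping(g.geometry),
            "properties": {"tract_id": g.tract_id, "area_sqft": g.area_sqft},
        }
        for g in geometries
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_tract_scores_geojson(
    geometries: Sequence[TractGeometry],
    scores: pd.DataFrame,
    path: str | Path,
) -> None:
    """Write the scored-tract map layer as a GeoJSON FeatureCollection.

    ``scores`` is indexed by tract_id and carries the joined HVI, component
    scores, LST, canopy and priority columns; every scored tract must have a
    geometry, otherwise a :class:`JoinError` lists the orphan GEOIDs.
    Coordinates are WGS84 longitude/latitude per RFC 7946.
    """
    geom_by_id = {g.tract_id: g for g in geometries}
    orphans = sorted(set(scores.index) - set(geom_by_id))
    if orphans:
        raise JoinError(f"scored tract(s) without geometry: {orphans}")
    features = []
    for tract_id, row in scores.iterrows():
        props: dict[str, object] = {"tract_id": tract_id}
        for key, val in row.items():
            if isinstance(val, (bool,)) or val is None or isinstance(val, str):
                props[key] = val
            elif isinstance(val, float) and float(val).is_integer() and "score" in key:
                props[key] = int(val)
            else:
                props[key] = val.item() if hasattr(val, "item") else val
        features.append(
            {
                "type": "Feature",
                "geometry": shapely_mapping(geom_by_id[tract_id].geometry),
                "properties": props,
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    logger.info("wrote %d scored tract features to %s", len(features), path)


def read_scores_geojson(path: str | Path) -> pd.DataFrame:
    """Read back the properties of a scored-tract GeoJSON (round-trip aid)."""
    with open(path, encoding="utf-8") as fh:
        fc = json.load(fh)
    rows = [feat["properties"] for feat in fc["features"]]
    return pd.DataFrame(rows).set_index("tract_id")
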