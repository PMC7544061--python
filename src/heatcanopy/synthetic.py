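"""Seed-deterministic synthetic inputs with the structure the HVI assumes.

Real inputs (a census five-year-estimate extract, a high-resolution land
cover product, remotely sensed summer land surface temperature) cannot ship
with a test suite, so these generators emulate their statistical structure:

* tract variables arise from a three-latent-factor model — a
  sociodemographic factor, an urbanicity factor and a population
  age-and-isolation factor — matching the dimensionality the rotated-PCA
  weighting stage is expected to recover;
* block-group land cover is a Dirichlet split of a lognormal block-group
  area over the five exclusive cover classes, so class areas sum to the
  block-group total exactly;
* tract LST is linear in canopy percentage with Gaussian noise, emulating
  the cooling relationship that motivates tree planting.

One integer seed drives every generator through numpy SeedSequence
spawning, so composed fixtures are reproducible end to end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from scipy.special import expit
from shapely.geometry import Polygon

from .io_schema import (
    LandCoverClass,
    LandCoverRecord,
    LstRecord,
    TractGeometry,
    TractVariableTable,
    ValidationError,
    VariableSchema,
    default_schema,
)

#: Squash scale for mapping latent values onto the 0-100 percentage range:
#: pct = 100 * expit(latent / SQUASH_SCALE). The divisor keeps typical latent
#: values (|x| < ~2.5 under the default factor model) on the near-linear part
#: of the logistic, so planted correlations survive the mapping.
SQUASH_SCALE = 2.0
#: Housing density is exp(DENSITY_LOG_MEAN + DENSITY_LOG_SCALE * latent),
#: giving a positive, right-skewed units-per-square-mile distribution.
DENSITY_LOG_MEAN = 7.0
DENSITY_LOG_SCALE = 0.5

_FACTOR_BLOCKS: dict[str, tuple[tuple[str, float], ...]] = {
    "sociodemographic": (
        ("pct_hispanic", 0.8),
        ("pct_black", 0.8),
        ("pct_foreign_born", 0.8),
        ("pct_limited_english", 0.8),
        ("pct_below_poverty", 0.8),
        ("pct_disability_18_64", 0.8),
        ("pct_unemployed_18_64", 0.8),
    ),
    "urbanicity": (
        ("pct_housing_pre1980", 0.8),
        ("housing_density", 0.8),
        ("pct_high_intensity_developed", 0.8),
        ("pct_open_undeveloped", -0.8),
    ),
    "age_isolation": (
        ("pct_over65", 0.8),
        ("pct_over65_alone", 0.8),
    ),
}


def default_loading_matrix(schema: VariableSchema | None = None) -> np.ndarray:
    """Planted 13x3 loading matrix with disjoint factor blocks.

    Factor 1 carries the seven sociodemographic percentages, factor 2 the
    housing/development variables (open undeveloped land loading negatively),
    factor 3 the two over-65 variables.
    """
    schema = schema or default_schema()
    lam = np.zeros((len(schema.names), len(_FACTOR_BLOCKS)))
    for j, block in enumerate(_FACTOR_BLOCKS.values()):
        for name, value in block:
            lam[schema.names.index(name), j] = value
    return lam


@dataclass
class CohortSpec:
    """Parameters of one synthetic tract cohort."""

    n_tracts: int = 500
    loading_matrix: np.ndarray | None = None
    noise_sd: float = 0.1
    seed: int = 0
    schema: VariableSchema = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        if self.n_tracts < 10:
            raise ValidationError(f"n_tracts must be >= 10, got {self.n_tracts}")
        if self.noise_sd <= 0:
            raise ValidationError(f"noise_sd must be positive, got {self.noise_sd}")
        if self.loading_matrix is None:
            self.loading_matrix = default_loading_matrix(self.schema)
        self.loading_matrix = np.asarray(self.loading_matrix, dtype=float)
        if self.loading_matrix.shape[0] != len(self.schema.names):
            raise ValidationError("loading matrix rows must match schema variables")
        if np.any((self.loading_matrix == 0).all(axis=0)):
            raise ValidationError("loading matrix has an all-zero factor column")


def synthetic_tract_ids(n: int, state_county: str = "25025") -> list[str]:
    """Format-valid synthetic tract GEOIDs (state+county prefix + 6 digits)."""
    return [f"{state_county}{i:06d}" for i in range(1, n + 1)]


def generate_latent(spec: CohortSpec) -> np.ndarray:
    """Pre-squash latent variable matrix: factors @ loadings' + noise.

    Latent factors are independent standard normal; per-variable Gaussian
    noise has SD ``spec.noise_sd``. This is the scale on which the implied
    correlation matrix lambda lambda' + psi holds exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n, (p, k) = spec.n_tracts, spec.loading_matrix.shape
    factors = rng.standard_normal((n, k))
    noise = rng.standard_normal((n, p)) * spec.noise_sd
    return factors @ spec.loading_matrix.T + noise


def implied_correlation(loading_matrix: np.ndarray, noise_sd: float) -> np.ndarray:
    """Population correlation matrix of the latent model (oracle helper)."""
    lam = np.asarray(loading_matrix, dtype=float)
    cov = lam @ lam.T + noise_sd**2 * np.eye(lam.shape[0])
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def generate_tract_cohort(spec: CohortSpec) -> TractVariableTable:
    """Generate a schema-valid synthetic tract table from the factor model.

    Percentage variables are squashed into [0,100] by a scaled logistic
    (monotone, so factor structure is preserved up to mild attenuation);
    housing density is exponentiated to be positive. Identical seeds give
    identical tables.
    """
    latent = generate_latent(spec)
    cols = {}
    from .io_schema import PERCENTAGE_VARIABLES

    for j, name in enumerate(spec.schema.names):
        x = latent[:, j]
        if name in PERCENTAGE_VARIABLES:
            cols[name] = 100.0 * expit(x / SQUASH_SCALE)
        else:
            cols[name] = np.exp(DENSITY_LOG_MEAN + DENSITY_LOG_SCALE * x)
    df = pd.DataFrame(cols)
    df.insert(0, "tract_id", synthetic_tract_ids(spec.n_tracts))
    return TractVariableTable(df, spec.schema)


#: Dirichlet concentration per cover class for block-group area splits.
DEFAULT_CLASS_MIX: dict[str, float] = {
    LandCoverClass.TREE_CANOPY.value: 2.0,
    LandCoverClass.VEGETATION.value: 2.0,
    LandCoverClass.IMPERVIOUS.value: 3.0,
    LandCoverClass.BUILDING.value: 2.0,
    LandCoverClass.OTHER.value: 1.0,
}
#: Lognormal parameters of block-group total area (median ~5M sqft).
BLOCKGROUP_AREA_LOG_MEAN = np.log(5e6)
BLOCKGROUP_AREA_LOG_SD = 0.5


def generate_landcover(
    tract_ids: list[str],
    blockgroups_per_tract: int = 3,
    class_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> list[LandCoverRecord]:
    """Synthetic block-group land cover: Dirichlet class split of a lognormal total."""
    if not tract_ids:
        raise ValidationError("tract_ids must be non-empty")
    if not 1 <= blockgroups_per_tract <= 9:
        raise ValidationError("blockgroups_per_tract must be in 1..9")
    mix = class_mix or DEFAULT_CLASS_MIX
    classes = list(mix)
    alphas = np.array([mix[c] for c in classes], dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    records = []
    for tract_id in tract_ids:
        for b in range(1, blockgroups_per_tract + 1):
            bg_id = f"{tract_id}{b}"
            total = float(
                np.exp(rng.normal(BLOCKGROUP_AREA_LOG_MEAN, BLOCKGROUP_AREA_LOG_SD))
            )
            shares = rng.dirichlet(alphas)
            for cls, share in zip(classes, shares):
                records.append(LandCoverRecord(bg_id, LandCoverClass(cls), share * total))
    return records


def generate_lst(
    tract_ids: list[str],
    canopy_pct: np.ndarray | pd.Series,
    slope: float = 0.1,
    noise_sd: float = 0.5,
    baseline: float = 32.0,
    seed: int = 0,
) -> list[LstRecord]:
    """Synthetic mean summer LST, cooling linearly with canopy percentage.

    LST = baseline - slope * canopy_pct + N(0, noise_sd), in deg C. With
    positive slope and vanishing noise, LST is strictly decreasing in canopy.
    """
    canopy = np.asarray(canopy_pct, dtype=float)
    if len(canopy) != len(tract_ids):
        raise ValidationError("canopy_pct length must match tract_ids")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    noise = rng.normal(0.0, noise_sd, size=len(canopy)) if noise_sd > 0 else np.zeros(len(canopy))
    return [
        LstRecord(tid, float(baseline - slope * c + e))
        for tid, c, e in zip(tract_ids, canopy, noise)
    ]


def generate_tract_geometries(
    tract_ids: list[str],
    origin: tuple[float, float] = (-71.10, 42.30),
    cell_deg: float = 0.01,
) -> list[TractGeometry]:
    """Synthetic square tracts laid out on a WGS84 grid near Boston.

    Areas come from the equirectangular approximation at the grid latitude,
    in square feet. Purely a plumbing stand-in for real tract boundaries.
    """
    lon0, lat0 = origin
    n_cols = max(1, int(np.ceil(np.sqrt(len(tract_ids)))))
    ft_per_deg_lat = 364000.0
    ft_per_deg_lon = ft_per_deg_lat * float(np.cos(np.radians(lat0)))
    area = cell_deg * ft_per_deg_lon * cell_deg * ft_per_deg_lat
    geoms = []
    for i, tid in enumerate(tract_ids):
        r, c = divmod(i, n_cols)
        x, y = lon0 + c * cell_deg, lat0 + r * cell_deg
        poly = Polygon(
            [(x, y), (x + cell_deg, y), (x + cell_deg, y + cell_deg), (x, y + cell_deg)]
        )
        geoms.append(TractGeometry(tract_id=tid, geometry=poly, area_sqft=area))
    return geoms


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]
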