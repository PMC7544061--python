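# Methods

## The index model and its assumptions

The Heat Vulnerability Index is a weighted-indicator composite, not a
fitted outcome model: it assumes the 13 indicators jointly proxy heat
vulnerability and that a low-rank linear structure (a few interpretable
components) captures their covariation. Because the indicators mix units
(percentages, housing units per square mile), PCA is performed on the
**correlation** matrix — equivalently on standardized variables — which is
the only defensible choice for mixed-unit indicator sets.

Pipeline decisions, in run order:

- **Standardization.** Sample SD (n−1 denominator) throughout; cohorts
  need ≥ 3 tracts and no constant indicator. Missing values are rejected
  by default; an explicit flag enables cohort-median imputation, logged
  per variable — an index that feeds policy should fail loudly rather
  than silently fill gaps.
- **Retention.** Kaiser criterion (correlation-matrix eigenvalue > 1) by
  default. "Interpretability" cannot be made algorithmic, so a fixed-k
  override exists for analysts who inspect loadings. If no eigenvalue
  exceeds 1, the error message points to the override rather than
  silently retaining one component.
- **Rotation.** Varimax (orthogonal), the standard choice for
  vulnerability-index construction and the default in the major
  statistical packages. Implemented in-package as the usual iterative-SVD
  algorithm (tolerance 1e-10, ≤ 500 iterations); orthogonality of the
  rotation preserves per-variable communalities exactly, which the test
  suite asserts to 1e-6.
- **Orientation.** A rotated component's sign is arbitrary. Each
  component is oriented so its summed loading over vulnerability-
  *increasing* variables is ≥ 0; the schema marks open undeveloped land
  as vulnerability-decreasing (it is protective: cooler and plantable).
  High scores therefore always mean high vulnerability.
- **Weights.** Full rotated loading vectors (no salience cutoff) are the
  default weights; a configurable |loading| threshold can zero small
  loadings for analysts who prefer sparse weights.
- **Scoring.** Two readings of "weight, standardize, sum" are
  algebraically distinct. The default standardizes the component *sum*
  (weighted sum of standardized variables, then cohort z-scoring), which
  makes the factor scores well-defined. The alternative — standardize
  each weighted variable, then sum — is exposed as
  `scoring="standardize_each"`; note that re-standardizing ℓ·z reduces
  every non-zero weight to its sign, so that mode is effectively
  sign-only weighting. Both are implemented; the sum-then-standardize
  reading is the default.
- **Binning.** Categories 1–6 on half-open, lower-closed SD bands:
  z < −2 → 1, [−2,−1) → 2, [−1,0) → 3, [0,1) → 4, [1,2) → 5, z ≥ 2 → 6.
  Only the outer bands are forced by the construction ("more than 2 SD
  below/above the mean"); lower-closure is the tie rule, sending interior
  boundary values to the more vulnerable bin. The rule is total,
  monotone and deterministic, verified against a lookup oracle on a
  10⁴-point grid.

Degenerate inputs fail with named errors: constant columns, < 3 tracts,
zero-variance component scores, NaN z-scores, categorical scores outside
1–6.

## Feasibility and priority

Block-group square footage is summed to tracts after a stable sort, so
aggregation is bitwise order-invariant. Tract total area is the sum of
the five cover classes (not the geometry area), keeping percentages
internally consistent: the five class percentages partition 100% to 1e-9.
Zero-area tracts are an error, not a silent 0%.

The feasibility threshold is deliberately cohort-relative by default
(high = top 50% by potential-canopy percentage) because no absolute
cutoff is canonical and a relative rule is scale-free across cities; an
absolute percentage override exists. Ties at any threshold classify
high — the tool's purpose is to recommend planting, so doubt breaks
toward action.

"High" HVI and "high" LST default to the cohort top quartile
(q = 0.75, linear-interpolation quantile, ties flagged). Quantile flags
are anti-monotone in q. An all-identical cohort has no meaningful high
end and raises rather than flagging everything. The priority rule is the
exact boolean `feasible ∧ (hvi ∨ lst)`; the two drivers are never summed
or averaged into one index because vulnerability and surface temperature
can anti-correlate and a merged score would obscure both.

## Species selection

Filters are conjunctive over optional constraints; an empty filter is the
identity. Light matching uses tolerance semantics (full_sun < partial <
shade_tolerant): a request states the light *available* at the site, and a
tree passes if it tolerates at least that much shade. The heat-reduction
score is the plain product transpiration_rate × leaf_area — the two
drivers of evapotranspirative cooling — with a top-quartile flag, ties
flagging true; the score is deliberately simple because no published
classification rule is available to reproduce.

The packaged table `data/species_synthetic.csv` has 34 rows with real
scientific names of commonly approved urban species but **synthetic**
attribute values (spread, light, allergenicity, transpiration, leaf
area). Results on it exercise the machinery and are not horticultural
claims; real deployments should supply a curated CSV.

## Synthetic data: what it emulates and what it does not

The cohort generator plants a three-factor latent model matching the
dimensionality the index is expected to recover: a sociodemographic
factor on the seven socioeconomic percentages, an urbanicity factor on
the four housing/development variables (open undeveloped land loading
negatively), and an age-and-isolation factor on the two over-65
variables. Defaults: n = 500 tracts, block loadings ±0.8, noise SD 0.1.
Latent values map to valid ranges by a scaled logistic for percentages,
`100·expit(x/2)` (the divisor keeps typical |x| < 2.5 on the near-linear
part of the curve, so planted correlations attenuate only mildly), and by
exponentiation for housing density, `exp(7 + 0.5x)` (median ≈ 1100
units/sq mi, right-skewed). Land cover is a Dirichlet split of a
lognormal block-group total (median ≈ 5M sq ft), so class areas sum to
the total by construction; LST is linear in canopy percentage
(baseline 32 °C, slope 0.1 °C per canopy point, noise SD 0.5 °C) with a
negative canopy–temperature correlation. One integer seed drives all
generators through numpy SeedSequence spawning.

What the generator does **not** emulate: spatial autocorrelation between
neighboring tracts, realistic marginal distributions of any real city,
correlation between the sociodemographic factors and land cover or LST,
and measurement error structure of survey estimates. Passing tests
therefore demonstrate that the machinery is correct (recovery of planted
structure, exact aggregation, deterministic scoring), not that the index
is valid for any particular city.

On the default cohort the sampled correlation matrix is compared to the
analytic ΛΛᵀ + σ²I correlation by *relative* Frobenius distance
(≤ 0.15): per-entry sampling error scales as 1/√n, so the absolute
distance grows with the entry count while the relative distance stays
small. Factor recovery is scored by Tucker congruence after optimal
one-to-one matching (Hungarian assignment on |congruence|) between
recovered and planted columns, with both sides orientation-fixed; the
retained-component count and congruence ≥ 0.95 hold across seeds.

## Problem sizes

Tests and the acceptance script run on synthetic cohorts of 100–500
tracts; the factor-recovery check repeats 100 seeds at n = 500. These
sizes give stable eigenstructure (n ≫ p = 13) while keeping the whole
suite under a few seconds.

## Known limitations

- The HVI has no uncertainty quantification; scores are points.
- No oblique rotations; correlated vulnerability dimensions are forced
  orthogonal.
- The feasibility metric ignores sub-tract constraints (utility
  clearances, ownership, soil) — it measures plantable *cover*, not
  plantable *sites*.
- GeoJSON/WGS84 is the only geometry format; no raster processing or
  shapefile support.
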