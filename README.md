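# heatcanopy

Decision support for equitable urban tree planting: where in a city should
new canopy go, and which species should go there?

Extreme heat is a leading weather-related cause of death in US cities, and
its burden is unevenly distributed. City forestry programs and residents
need to weigh three distinct things when deciding where to plant: **who is
vulnerable** to heat (a sociodemographic question), **where it is hot** (a
remote-sensing question), and **where planting is physically feasible** (a
land-cover question). `heatcanopy` computes all three at the census-tract
level and combines them into per-tract planting priorities, then filters a
city-approved tree-species list by hyper-local site constraints.

## The model

**Heat Vulnerability Index (HVI).** For each tract, 13 indicators
x₁…x₁₃ (percent Hispanic, Black, foreign-born, limited-English,
below-poverty, over-65, over-65 living alone, disabled 18–64, unemployed
18–64, pre-1980 housing, housing-unit density, high-intensity development,
open undeveloped land) are standardized across the cohort,
z_v = (x_v − x̄_v)/s_v. Principal components of the 13×13 correlation
matrix are retained by the Kaiser criterion (eigenvalue λ > 1) and varimax-
rotated; each rotated component c is sign-oriented so its loading sum over
vulnerability-increasing variables is non-negative. Per-tract component
scores

  f_c(t) = Σ_v ℓ_{vc} · z_v(t)

are re-standardized to cohort mean 0, SD 1, then binned into categories
1–6 by standard deviations from the mean (below −2 SD → 1, above +2 SD
→ 6, half-open unit bands between). The HVI is the sum of the k
categorical scores, ranging k…6k; with the three components a typical
cohort yields (sociodemographic, urbanicity, age-and-isolation) the range
is 3–18.

**Feasibility.** High-resolution land cover (square feet per block group
in five exclusive classes) is summed to tracts. *Potential canopy* is the
vegetation (grass/shrub) class — plantable today; impervious surface never
counts. Tracts in the top half by potential-canopy percentage (default;
configurable absolute cutoff) have *high* feasibility.

**Priority.** A tract is a planting priority iff

  priority = high_feasibility ∧ (high_HVI ∨ high_LST)

where "high" is the cohort top quartile (configurable). HVI and land
surface temperature are kept as separate flags — they can anti-correlate
across a city and merging them would obscure both. Low-feasibility tracts
get `alternative_interventions` (cool roofs, depaving, green roofs)
regardless of vulnerability.

**Species selection.** The 34-species approved list is filtered
conjunctively by canopy spread, light tolerance (a shade-tolerant tree
satisfies any light request), street/park siting, pollen allergenicity,
breakage resistance and growth rate. Species whose
transpiration-rate × leaf-area product is in the top quartile are flagged
for high heat-reduction potential. The packaged species table carries
synthetic attribute values (see `docs/methods.md`); swap in a curated CSV
for real use.

Because census extracts and land-cover rasters cannot ship with the
package, a seed-deterministic synthetic generator emulates every input,
including the three-factor latent structure the PCA stage is expected to
recover.

## Worked example

```sh
heatcanopy simulate --seed 42 --n-tracts 100 -o demo
heatcanopy run-all -c demo/config.yaml
```

writes `hvi.csv`, `weighting_model.csv`, `canopy.csv`, `priority.csv`,
`species_selection.csv`, `tracts_scored.geojson` and a `manifest.yaml`
(config echo, library versions, input checksums) under `demo/results/`.
The first scored tract looks like:

```
tract_id,...,z_component_1,z_component_2,z_component_3,cat_component_1,cat_component_2,cat_component_3,hvi
25025000001,...,1.4289,0.5511,-0.2882,5,4,3,12
```

Tract `25025000001` sits 1.43 SD above the cohort mean on the
sociodemographic component (category 5), near the mean on the other two
(categories 4 and 3), for an HVI of 12 out of 3–18. Across this cohort the
HVI ranges 6–15 and 27 of 100 tracts are planting priorities, e.g.:

```
tract_id     high_hvi  high_lst  high_feasibility  priority recommendation
25025000001      True     False              True      True    plant_trees
25025000009      True      True              True      True    plant_trees
```

The first tract is flagged for vulnerability alone (its surface
temperature is unremarkable) but is feasible to plant, so it is a
priority. Species for a narrow street site:

```sh
heatcanopy select-species --site street --max-spread 35 --max-allergenicity medium
```

```
species                          common name                spread light          heat icon
-------------------------------------------------------------------------------------------
Acer campestre                   hedge maple                    30 full_sun
Amelanchier laevis               Allegheny serviceberry         20 partial
...
```

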