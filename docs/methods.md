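# Methods

This note documents the models implemented in `ncpscape`, the assumptions
behind them, the synthetic data the tests run on, and the numerical and
design choices that were genuinely open.

## Pipeline overview

Five stages: synthetic region generation (or reading user rasters) →
per-NCP supply/demand indicators → budget/ratio indices → temporal trend
coefficients → archetype clustering. All rasters share one grid in a local
metric CRS with square pixels (default 1 ha); every pixel belongs to exactly
one municipality (assignment by pixel center), so zonal statistics are exact
bincount reductions.

## Indicator models

**Pollination.** Supply is a pollinator-abundance index: per pixel,
nesting suitability `N(class)` times the kernel-weighted average of floral
resources, with kernel `exp(−d/α)` truncated at `2α` (defaults α = 500 m).
Kernels are normalized by the kernel mass actually inside the grid, which
makes a uniform landscape an exact fixed point (abundance = N·F) including
at edges. Demand is the pollinator-dependent share of cropped area,
rescaled by the largest dependence fraction so the index reaches 1 when all
cropland is in the most dependent class; no cropland means no demand.

**Habitat preservation.** Supply maps protection levels 0..4 to
{0, 0.25, 0.5, 0.75, 1} and averages per municipality. Demand is degradation:
per threat, intensity averaged through a linear (`1 − d/d_max`) or
exponential (`exp(−2.99 d/d_max)`, ~5% weight at `d_max`) decay kernel,
weighted by the exposed pixel's class sensitivity and the threat weight,
summed over threats. The result is rescaled by the regional maximum pooled
over **all timesteps** of the run — per-timestep rescaling would erase
exactly the temporal signal the trend stage needs. An explicit
`rescale_max` argument lets callers hold the denominator fixed, which is
the reading under which degradation demand is pointwise monotone in the
threat layers (with a run-relative maximum it cannot be: raising a threat
elsewhere raises the denominator everywhere).

**Recreation.** Supply: per-pixel value v = weighted mean of a land-cover
recreation value, a water-proximity indicator (within 500 m of water) and a
public-park flag, weights 0.6/0.2/0.2. The land-cover layer dominates
deliberately: with equal weights, ordinary forest (class value 0.8 → v 0.27)
would fall below the 0.4 usability threshold and rural recreation supply
would be governed entirely by the accidental placement of lakes. Pixels
with v ≥ θ (default 0.4) contribute `v × pixel area × u` (usable-space
fraction u = 0.5); the municipal figure is the zone **mean** (m² per pixel)
— the zone-sum reading is available by multiplying by the pixel count.
Demand: per pixel, the population within walking distance (1000 m disk,
boundary-aware normalization by the in-grid buffer pixel count) times the
per-capita recreation need (30 m²/person), zone-averaged. A uniform
population p therefore demands exactly 30p everywhere.

**Food.** Supply: Σ yield(kg/ha) × cropped area + Σ meat(kg/animal) ×
stocking density(animals/ha of pasture) × pasture area. Demand: per-capita
consumption × municipal population.

**Water regulation.** Supply uses the Fu form of the Budyko curve with
aridity φ = PET/P: `AET/P = 1 + φ − (1 + φ^ω)^{1/ω}`; annual yield
Y = P − AET (mm), ω = 2.6 on vegetated classes and 2.0 otherwise
(vegetation retains more water). Non-positive precipitation yields 0 with a
logged warning. Municipal supply = zone-mean yield × zone area × 10⁻³
(1 mm over 1 m² = 1 litre). Demand = per-capita household rate × population
plus per-pixel sectoral rates by land-cover class.

**Climate regulation.** Supply: class-wise NPP (tC/ha/yr) × area, as the
carbon-sequestration proxy. Satellite NPP exists only from the 2000s on, so
the pipeline by default treats the first two of four timesteps as
unobserved and back-fills them by per-municipality OLS over the observed
ones, clipped at 0 (`npp_observed_from: 2`; set to `null` to use all
land-cover-derived values directly). Demand: per-capita CO₂-equivalent ×
population × 12/44 (molar conversion to carbon).

## Indices

FOD, WAT and CLI are converted to per-capita values before indexing, so
large municipalities do not dominate the scales. The budget is the
difference of supply and demand after **joint** min–max normalization per
NCP — one (min, max) shared by supply and demand, pooled over all
municipalities and timesteps. Sharing the scale bounds the budget in
[−1, 1] and keeps its sign faithful to the raw comparison; pooling over
timesteps preserves trends (per-timestep normalization would make B_coeff
meaningless). The normalization statistics are written to a JSON sidecar.

The ratio is computed on raw same-unit values and shifted:
`R = S/D − 1`, so 0 marks exact balance and −1 no supply — the shift is the
only reading consistent with a lower bound of −1; the unshifted variant is
available (`index.shifted_ratio: false`). `D = 0` with `S > 0` is undefined
and mapped to a configurable cap (default 99) with a flag column; 0/0 maps
to 0. Because the shared scale is order-preserving, sign(budget) =
sign(ratio) wherever demand is positive; this is property-tested.

## Trends

B_coeff and R_coeff are OLS slopes of the budget and ratio series against
the ordinal timestep index 0..3 (decadal timesteps are treated as evenly
spaced; a calendar-year regressor can be configured). No p-values are
attached: four-point slopes are used descriptively. A stability label
summarizes the pair: both coefficients positive beyond a deadband ε = 1e−6
→ stable improving, both negative → stable declining, both within ε →
neutral, anything else (including one neutral side) → mixed. ε is an
artifact convention; the coefficients' "neutral" is not defined numerically
anywhere else.

The cube-root transform `sign(x)|x|^{1/3}` is applied only in exported
plot data (bubble-plot axes), never in clustering.

## Clustering

Features: 3 variables × n NCPs per municipality (18 by default), z-scored
per column (raw-scale clustering available via `clustering.standardize:
false`; a constant column is an error by default, zero-filled on request).
Ward linkage on Euclidean distances is the default (average/complete
available) — the standard choice in ecosystem-service bundle analyses.
The cluster count is fixed by hand or chosen by mean-silhouette
maximization over k = 2..8 (alternative: largest relative merge-height
gap); ties go to the smaller k. Silhouette maximization is a reproducible
stand-in for visual dendrogram inspection, which cannot be automated
faithfully. Cluster ids are canonical — descending size, ties broken by the
lowest member id — so outputs are stable across platforms and row orders.
Profiles report unstandardized per-cluster feature means plus land-cover
composition at the last timestep; no interpretive cluster names are
assigned.

## Synthetic regions

The generator emulates a canton-scale study area: 200×200 one-hectare
pixels (400 km²), 60 municipalities from a Voronoi partition of random seed
points (guaranteed full partition, irregular shapes), four decadal
timesteps, regional population growing 60% over the period, and four
planted archetypes — an urbanizing core, stable forested highlands,
intensifying agricultural patches and a blue-green lake/park belt. Each
archetype is an initial land-cover composition plus a per-decade Markov
transition of class fractions; municipalities follow their archetype's
trajectory with multiplicative lognormal noise. The noise budget is split
deliberately: a municipality-level factor (sd = noise_sd) perturbs
*composition* at every timestep, while the per-timestep jitter is ten times
weaker — archetypes are planted as temporal signatures, and noise that
randomized trajectories would contradict the design. `archetype_mixing`
(default 0.1) blends each municipality toward the regional mean
composition.

Fractions are spatially allocated per zone by a fixed priority order
(water, settlement, parks, crops, forest, meadow, rest) over static smooth
suitability fields, so maps change contiguously around existing patches;
settlement suitability rises toward each zone's seed point (urban cores).
Settlement counts are kept non-decreasing in time: urbanization is treated
as irreversible. Population follows a smoothed settlement kernel plus a
uniform rural baseline (0.1 relative units ≈ plateau rural densities);
the baseline matters — with near-empty rural municipalities, per-capita
and recreation ratios become heavy-tailed and municipality noise swamps the
planted structure. Protection is static (archetype-specific protected
shares, banded into levels 1–4, preferring natural covers); threats derive
from land cover (settlement = urban threat 1.0; crops = agricultural threat
0.8); climate is a static gentle gradient (P ≈ 1050–1250 mm,
PET ≈ 550–620 mm) — at canton scale, land-use differences, not climate,
should drive water-yield contrasts.

What the generator does **not** emulate: real geography or any actual
municipality list, sub-decadal dynamics, climate change over the period,
crop calendars, migration that decouples population from settlement area,
and protected-area expansion. Passing tests therefore demonstrate the
pipeline's correctness and the recoverability of planted structure, not
calibration to any real region.

## Numerical choices and problem sizes

Kernel averages are exact direct convolutions (no FFT), verified against
brute-force pixel-pair summation to 1e−9 relative tolerance on small grids.
Integer apportionment of class fractions uses largest-remainder rounding.
Degenerate normalization (max = min) maps to 0 with a warning. All
randomness flows from one seed through named substreams (zones, labels,
fractions, suitability, protection, climate), so individual layers are
reproducible in isolation. Tests and the acceptance script use reduced
problem sizes where the property under test does not depend on scale
(48×48 grids with 16 municipalities for range sweeps and monotonicity;
the full 200×200 default for archetype recovery); the full default region
runs end to end in about one second.

## Known limitations

- The six indicator engines are deliberately simplified stand-ins for full
  ecological models; they share the originals' structure (kernels, decay,
  Budyko) but none of their calibration.
- Only local (within-municipality) supply–demand balances are computed;
  proximity and interregional flows are not modeled, though walk-distance
  recreation demand and threat kernels do leak across borders.
- The ratio's cap at demand = 0 is a pragmatic sentinel, not a measurement.
- Cluster counts chosen by silhouette can differ by ±1 from visual
  dendrogram judgment on noisy regions; the manual `clustering.k` override
  exists for exactly that case.
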