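# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of `modscape`.

## Scope and model chain

The package implements the standard scenario-analysis chain for
mountain-oasis-desert (MODS) landscapes: Markov-chain land demand under
policy scenarios, FLUS-style ANN + cellular-automaton spatial allocation,
six per-pixel ecosystem-service (ES) models, and regional plus grid-scale
multi-ES trade-off/synergy identification. All stages operate on synthetic
landscapes; nothing in the package attempts to reproduce any real region's
geography, meteorology or reported service magnitudes.

## Synthetic landscapes

`generate_landscape` emulates the *statistical* structure of an arid MODS
prefecture:

- **Terrain**: elevation descends linearly from the northern edge with
  spatially correlated relief (Gaussian-filtered white noise, correlation
  length ≈ grid/12). Default range 500–3500 m.
- **Climate**: precipitation = 140 mm/a + 0.045 mm/a·m⁻¹ × elevation above
  base + correlated noise (σ = 6 mm), clipped at 5 mm/a — so precipitation
  increases with altitude by construction (Spearman ρ ≈ 0.99 on default
  grids, far above the ρ > 0.5 the downstream stages assume). Temperature
  follows a 6.5 °C/km lapse; reference ET rises with temperature.
- **Zonation**: mountains = top elevation tercile; oasis = lower ground
  within 6 pixels of a meandering north-south river line; desert = the rest.
- **Land use**: per-class affinity scores (cropland/built-up hug the river
  inside the oasis, forest sits high and wet, bare land fills the desert,
  plus correlated noise) and an exact-count greedy fill, rarest class first.
  Realized composition therefore matches the requested mix to within
  rounding — well inside the ±2-percentage-point tolerance the tests check.
  The default mix is 3.6 % cropland, 7.3 % forest, 34.9 % grassland,
  52.3 % bare, and 1.9 % split between water (1.2 %) and built-up (0.7 %),
  the composition of the emulated prefecture's base year.
- **Soil and wind factors**: texture fractions, organic matter and the four
  RWEQ factor rasters are zone-trended correlated fields (e.g. sandier and
  windier in the desert).

All randomness flows through one `numpy.random.Generator` seeded per call;
identical config + seed ⇒ bit-identical bundles.

What the generator does **not** emulate: real river networks and irrigation
command areas, interannual climate variability, spatially autocorrelated
*class patches* beyond what the affinity scores induce, measurement error in
land-use maps. Passing tests therefore demonstrate correctness of the
algorithms under known structure, not predictive skill on real geodata.

`generate_markov_pair` is deliberately aspatial (i.i.d. pixels): it is the
fixture for transition-matrix estimation, where spatial structure would only
obscure the law-of-large-numbers check.

## Land-use simulation

**Transition matrix.** Cross-tabulation of two aligned maps, row-normalized;
classes absent at the period start receive identity rows rather than
invented dynamics.

**Scenario modifiers.** Shipped defaults: ED raises conversions of forest,
grassland, water and bare land into cropland by 50 % and conversions of
cropland, forest, grassland and bare land into built-up by 200 %; EC stops
conversions of forest/grassland/water into cropland and built-up (−100 %),
halves bare-land conversions into both (−50 %), and raises cropland
reversion to forest/grassland/water by 80 %; BAU changes nothing. Rows are
re-balanced through the **diagonal** (stay probability), which preserves the
stated relative changes on the targeted conversions exactly; only if the
diagonal would go negative are the off-diagonal entries rescaled
proportionally so it is exactly 0.

**Step splitting.** The calibration matrix covers 15 years; projections run
in 5-year steps, so the matrix is replaced by its regularized n-th root
(principal fractional matrix power, negatives clipped, rows renormalized;
n = 3 for the defaults). The Frobenius residual ‖Qⁿ − P‖ and a
regularization flag are recorded in the matrix metadata. For the
diagonally dominant matrices land-use change produces, the residual is at
machine precision.

**Suitability ANN.** One hidden layer of 2 × n_factors units
(`sklearn.neural_network.MLPClassifier`), min-max factor normalization,
uniform pixel sampling (default 5–10 %) with a stratified top-up so every
present class contributes at least `min_class_samples` pixels (rare classes
such as built-up would otherwise vanish from small training draws). Output
probabilities are renormalized to sum to 1 per pixel; classes absent from
the map get a uniform floor and a warning.

**Cellular automaton.** Per iteration and pixel, the combined probability of
class j is

```
suitability_j × (w_j · neighbourhood_share_j + 0.01) × inertia_j × cost_gate
```

with the neighbourhood share counted over a 3×3 Moore window (centre
excluded). The 0.01 floor lets a class seed outside its current extent. A
seeded roulette wheel proposes one class per pixel; proposals are accepted
while they move under-allocated classes toward demand at the expense of
classes with surplus, capped per donor class at its surplus. Inertia is
self-adaptive: a class whose |deficit| grows while under-allocated has its
inertia multiplied by 1.1, one that overshoots divided by 1.1 (bounds
10⁻³–10³); the constants are ours and configurable. Convergence = every
class within `demand_tolerance` (default 0.5 %) of its own demand, with a
one-pixel floor so tiny classes are not stuck on sub-pixel tolerances.
Cost-forbidden transitions are excluded from acceptance outright, so they
can never occur regardless of the roulette draw. Infeasible demand surfaces
as `converged: False` plus the per-class deviations.

Shipped conversion costs allow every transition (the historical-data-derived
cost and neighbourhood-weight tables of real studies are study-specific;
ours are configurable placeholders).

## ES models — defaults and rationale

The six service models follow the standard annual, per-pixel formulations;
where a published study delegates a sub-model to external software or
supplements, we ship a common formulation and accept precomputed rasters to
bypass it:

- **Water yield**: `Y = (1 − AET/P)·P`. AET/P defaults to the Budyko–Zhang
  curve `(1 + wφ)/(1 + wφ + 1/φ)` with aridity `φ = Kc·ET₀/P`; per-class
  `Kc` (0.2 bare … 1.1 water) and plant-available-water coefficient `w`
  (0.5 bare/built … 2.0 forest). The wrapper is model-agnostic
  (`aet_model=` swaps the curve). `P = 0` pixels yield 0 and are flagged.
- **Crop production**: Miami productivity, `3000/(1+e^{1.315−0.119T})` vs
  `3000(1−e^{−0.000664P})`, Liebig minimum, times a land-quality index
  `I_zrd ∈ [0,1]` (pipeline default 0.7 uniform); zero off cropland.
- **Soil conservation**: USLE with R from annual precipitation
  (`0.0483 P^1.61`), EPIC K from texture/organic matter, McCool LS from the
  DEM at pixel resolution; per-class C (1.0 bare … 0.006 forest) and support
  practice P (0.35 cropland, reflecting terracing/contouring on farmed
  land). `A_c + A = A_r` holds pixelwise by construction.
- **Sand fixation**: RWEQ transport at a fixed downwind distance
  x = 50 m (the transport equation's height symbol is read as this same
  distance; only the field length is configurable). Bare potential `Q₀`
  forces the vegetation factor to 1 but keeps crust and roughness at mapped
  values — "without vegetation" modifies vegetation only. Per-class
  vegetation factors: 1.0 bare, 0.25 cropland, 0.15 grassland, 0.05 forest.
- **Carbon**: four pools per class (defaults in kg/m², e.g. forest
  6 + 1.5 + 12 + 0.8), regional total `CT = Σ density × area`, linear in
  both table and areas.
- **Aesthetic value**: per-class survey-score means on a 0–5 scale
  (defaults: forest 4.6, water 4.2, cropland 3.8 — irrigated cropland rates
  highly with residents of arid regions — grassland 2.5, built-up 2.2,
  bare 0.8); subtype scores combine by area weights, which is how a
  heterogeneous class like grassland (high-scoring alpine meadow vs
  low-scoring desert steppe) gets its single class score.

All ES operations are deterministic, pixelwise and tiling-invariant.

## Interactions

Regional series are whole-area totals per projection year, min-max
normalized (`(v − min)/(max − min)`; constant series map to all zeros, an
explicit convention for the degenerate case). Trend labels use a 1 %
total-relative-change threshold for "virtually unchanged"; series with large
swings in both directions are labelled mixed, warned about and excluded from
pairing. Pairs: co-increase/co-decrease = synergy, opposite = trade-off,
any unchanged member = neutral.

Grid-scale coding: digit 1/2/3 = increase/decrease/unchanged per ES with
ε = 0 by default (raw sign of the change; configurable), concatenated in the
fixed order **(WY, CP, SC, SF, CS, AV)** — recorded in the raster metadata
since any fixed order works, but one must be chosen. Codes whose summed area
is **strictly** greater than 40 km² survive the area filter (default; the
"over X km²" reading), the rest pool into "other interactions". Labels list
increased services first in the presentation order (SC, CP, CS, AV, WY, SF),
e.g. `SC+ CP+ CS+ AV+, WY− SF−`. Cause attribution cross-tabulates retained
interaction classes against from→to land-use transitions and flags each
class's dominant transition.

## Pipeline

The driver fabricates the calibration pair by stepping the synthetic base
map through a configured historical matrix (default: mild oasis expansion —
bare → cropland/built-up — with slight grassland degradation), estimates the
matrix back, projects demand per scenario, allocates with the CA, quantifies
all six ES per projection year with climate/soil/terrain held fixed (land
use is the only changing driver), and runs both interaction analyses.
Validation reallocates the base year from the calibration start and reports
kappa plus per-class ROC-AUC. A manifest records config, seed, derived
stage seeds and SHA-256 hashes of every output; reruns are bit-identical.

Default problem sizes — 100×100 pixels for library-level analyses and 50×50
for end-to-end runs — keep a full three-scenario pipeline in the low seconds
while leaving every class populated enough to train on; both scale up by
config.

## Numerical conventions

- Areas are `pixel_count × pixel_size²`; planar projection assumed, no
  geodesic correction.
- Rasters: float32 (continuous), uint8 (categorical), int32 (codes); TIFF
  with a JSON sidecar for grid metadata. Roundtrips are value-exact for the
  stored dtype; cross-grid operations fail loudly.
- Row-stochasticity is enforced at 1e-9; per-pixel probability sums at 1e-6.
- Seeds: one `Generator` per call; the pipeline derives per-stage seeds from
  the master seed so stages are individually reproducible.

## Limitations

- The CA is a faithful small-scale implementation of the FLUS recipe, not a
  re-implementation of the GeoSOS-FLUS software (no tiling, threading, GUI).
- Sub-model formulations (AET curve, Miami P_v, R/K/LS, RWEQ factor
  preprocessing) are standard published stand-ins; studies using different
  supplements will differ numerically. All accept precomputed rasters.
- Synthetic landscapes validate algorithmic correctness, determinism and
  qualitative scenario behaviour (e.g. ED ⇒ more cropland/built-up than BAU
  at every horizon), not real-world magnitudes.
- No hydrological routing, sediment delivery, seasonal stepping, economic
  valuation, or ES-bundle/correlation statistics.
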