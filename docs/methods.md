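# Methods

This note documents the accounting model implemented by `nbudget`, its
parameters and defaults, the numerical conventions, what the synthetic
generator does and does not emulate, and the open design choices we made.

## The budget

For each country and year the cropland soil-surface N budget confronts
the N removed in harvest with four inputs:

    input_total = fert_C + manure_C + BNF + deposition_C
    surplus     = input_total − harvest_N

Quantities are in Gg N/yr, areas in kha, rates in kg N/ha/yr (1 Gg over
1 kha = 1000 kg/ha; the conversion lives in one helper).  "Cropland"
includes arable land and permanent crops, and in particular temporary
grassland; permanent grassland is outside cropland but is carried along
because fertilizer and manure allocation require it.  Soil N stock
changes, leaching and gaseous field losses are out of scope: the budget
is inputs versus harvest only.

Missing terms are flagged, never zero-filled; a budget row exists only
for years where all five terms exist.  Nitrogen use efficiency
(harvest/inputs) is emitted as a convenience column, missing when inputs
are zero.

## Panels and units

All data move between stages as `PanelSeries`: one variable, one country,
one explicit year grid (default 1961–2019, configurable per country, e.g.
1992–2019 for late-starting countries).  Missing is NaN internally and an
empty field in tidy CSV — never 0 or a sentinel.  Composite regions
(e.g. a Belgium–Luxembourg unit) are first-class region codes with
declared constituents, merged by summation or excretion/area-weighted
averaging.  CSV round trips are bit-exact: values are written with
shortest round-trippable float representation and read back with
round-trip float parsing.

## Crop categories

Crops map to 17 categories (12 from FAOSTAT-style crops, 5 fodder
categories from the Eurostat-style code hierarchy; lucerne G2100 and
other forage legumes G2900 merge into "Forage legumes").  Crop N contents
are constant over countries and years.  The category estimators:

* `A_sum`, `H_sum`: sums of available crop areas / N harvests.
* `Y_est = ΣH/ΣA` over crops with both area and harvest — a ratio of
  sums, which equals the area-weighted mean of crop yields.  It is
  computed per year; years where no crop has both are flagged and fall
  back to `A_est = A_sum`.
* `A_est = H_sum/Y_est`: the category area assuming crops with missing
  areas yield like the rest of the category.

Case-by-case adjustments (substituting national series, extrapolating a
missing edge, discarding outliers) are declarative edit rules, not code;
categories with no data at all get explicit zero series.

## Gap-filling rules

Interior gaps are filled only by linear interpolation; edges only by
constant extrapolation — anything else must be an explicit rule.
`proportional_split` divides a lumped series by fixed shares or by shares
taken from a reference year's component values; the last-listed component
takes the residual so the components reconstruct the total exactly.
`residual` (e.g. fodder roots as R0000 − R1000 − R2000) clips negative
results at zero with a logged warning, since areas cannot be negative.
`merge_sum` treats missing as absent unless both operands are missing.
Rules are applied in listed order and are fully deterministic.  Example
country configs (a fixed 29/6/42/23 hay split, a reference-year split, a
national replacement series) ship as data, illustrating how historical
narratives are expressed.

## Fodder crops

Humidity bases: national water content (0–88%), EU standard for plants
harvested green (65% water → 35% DM), hay (85% DM), dry matter, and a
16% DM default for fodder roots whose humidity is never reported.  An
advisory screen flags likely reporting errors: identical yields across
bases whose humidity differs, year-to-year steps matching the implied DM
factor, and implausible DM yields; the screen never auto-selects — the
selection of observations is configuration.

The 2010 reference yield per country and crop is the unweighted mean of
the selected DM-converted observations.  The trend is linear with the
1961 yield at 75% of the 2010 value (anchor configurable) and continues
with the same slope to 2019.  Temporary-grassland (G1000) yields are
multiplied by 1.20 in all countries to account for grazing in addition to
the mechanical harvest (order relative to DM conversion is immaterial for
a product; a config switch can disable it).  Remaining yield gaps are
filled from donor countries (single donor or unweighted mean).  G9000
yields derive production-weighted from G9100/G9900 where both exist.
Fodder N contents (% of DM) are 2.3 (G1000), 3.0 (G2100), 3.2 (G2900),
1.2 (G3000), 2.0 (G9000), 1.3 (R9000); the mixture values derive from
weighted means of component N contents (e.g. 75% grass at 2.0 + 25%
clover at 3.3) rounded to one decimal, and the weighted-mean helper is
part of the public surface.

## Land

Cropland in use is min(crop area sum, reported cropland) — the sum can
exceed the report through multi-/intercropping.  Temporary grassland is
the gap-filled G1000 area; permanent grassland is an input series.  When
fallow data exist, |crop area sum − (cropland − fallow)| > 5% is flagged.
When permanent plus temporary grassland is zero, grassland splits
degenerate to all-zero flows with a flag.  Land-use series ending a year
early are extended by constant extrapolation.

## Fertilizer allocation

share_C = (1 + (R_PG/R_C)·A_PG/A_C)^−1, applied to reported cropland and
permanent-grassland areas.  Rate-ratio estimation preference order:

1. direct R_PG/R_C from survey rates;
2. total-grassland (PG+TG) vs non-grass (C−TG) rates, assuming
   R_TG = k·R_PG: with m = A_PG+TG/(A_PG + k·A_TG),
   R_PG/R_C = (R_C−TG/(m·R_PG+TG)·A_C−TG/A_C + k·A_TG/A_C)^−1;
3. one category rate plus total consumption:
   R_x/R_complement = R_x(A_tot − A_x)/(Q_tot − R_x·A_x).

k defaults to 1 with per-country overrides in config.  Fertilized-subset
records (PGf) are first renormalized to the full category
(R_PG = R_PGf·A_PGf/A_PG).  Records carrying all of R, Q, A must satisfy
Q = R·A within 0.5% (configurable) or they are excluded with a logged
reason.  Multiple ratio estimates in one year are averaged as ratios (the
alternative — averaging rates — would weight publications by rate level;
we follow the ratio reading).  Ratio points interpolate linearly and
extrapolate constant; countries configured as applying no synthetic N to
permanent grassland get share 1 for all years.  Q_C = share·Q_tot and
Q_PG is the exact remainder.

## Manure

Detailed manure-management systems aggregate to grazing / solid / liquid
/ other, detailed livestock classes to ruminants-and-equines / pigs /
poultry-and-rabbits (excretion-weighted where several detailed classes
merge).  Shares observed from ~1990 are extrapolated constant backward to
1961 and forward one year.  Chain per country-year-class:

    grazing = total·share_grazing;    housed = total − grazing
    lost    = housed·loss_share;      applied = housed − lost
    applied_grass = applied·grass_share;  applied_nongrass = remainder
    grass-destined = applied_grass + grazing, split PG/TG by area;
    to_cropland = applied_nongrass + TG portion

Loss shares are constant country-specific values with a generic 30%
fallback.  The grass/non-grass allocation share is constant over the
whole period; for ruminants and pigs it is the liquid/solid-specific
shares weighted by the mean liquid split over 1997–2001 (window
configurable).  The liquid/solid split ignores the "other" system when it
is ≤20% of in-house excretion (renormalizing liquid+solid to 1); above
the threshold exogenous liquid/solid data are required and their absence
is an error naming the country and class.  Donor-country mappings cover
countries absent from the allocation data.  One known tension: grazing on
non-grass cropland (aftermath/stubble) is named as a pathway but the
final split assigns all grazing to grassland areas; we follow the final
split rule.

## Fixation and deposition

BNF = Y·Ndfa·BGN/NHI, linear in the harvested legume N Y.  For fodder
swards Y = DM harvest × legume DM share × legume N content (shares: 0.25
for G1000, 1.0 for G2100 as a pure stand — our reading, since only mixed
swards have stated shares — 0.90 for G2900, 0.25 for G9000; legume N
contents 3.3% for clover-type, 3.0% otherwise).  For pulses the harvested
category N is used directly.  The alternative pairing (category N ×
DM share) is available behind a config flag.  Ndfa/BGN/NHI are an input
parameter table; the shipped defaults are synthetic placeholders of
plausible magnitude (e.g. forage Ndfa 0.8, BGN 1.4, NHI 0.9) and are
clearly labelled as such — users with literature values should supply
their own table.  Deposition input is rate × cropland in use with rates
extrapolated constant past their last observed year.

## Numerical conventions

* Conservation is enforced by residual construction: each split computes
  one part as a product and the other as the exact remainder.  The
  identities are therefore checked in the residual direction
  (`housed == total − grazing`, `Q_PG == Q_tot − Q_C`, …), which binary
  floating-point arithmetic reproduces bit-exactly; re-adding
  independently rounded parts (`grazing + housed == total`) can differ in
  the last bit roughly 2% of the time and is checked only to 1e-12
  relative.
* Totals over categories, fixation sources and livestock classes are
  summed in a fixed declared order, making rebuilds bit-identical.
* All randomness is confined to the synthetic generator and funnelled
  through a single integer seed.

## The synthetic generator

The default scenario is 4 countries × 59 years (1961–2019) × 16 crops
(10 non-fodder mapping into 7 categories, 6 fodder codes) — small enough
for sub-minute test runs.  Trends are smooth quadratics with seeded
coefficients; the rate ratio declines exponentially (smooth enough that
5-yearly survey sampling plus linear interpolation stays well inside the
asserted 0.02 share tolerance); hay-component shares are constant before
1987 so a reference-year proportional split can recover them, and drift
afterwards.  Ground truth is produced by running the pipeline stages on
the complete inputs, so it satisfies every invariant by construction;
correctness of the stages themselves is established separately by
per-operation oracle tests (closed forms, forward constructions, brute
force).  Degradations: masking of pre-1985 crop areas (default 30%),
interior fodder-area masking (15%), pre-1987 hay lumping, mixed humidity
bases around 2010, surveys every 5th year (optional multiplicative
lognormal noise on rates, default off), manure shares from 1990 only,
deposition rates through 2013.  Masking never alters retained values.

What the generator does not emulate — and hence what passing tests do not
show about real data: systematic reporting biases, nomenclature changes
mid-series, conflicting sources for the same quantity, non-smooth
historical shocks, and the manual source-selection judgements that real
compilations require.  The recovery tests demonstrate that the mechanics
invert the degradations they model, not that the method is robust to
arbitrary real-world data pathology.

## Known limitations

* No crop-level fertilizer disaggregation (data do not support it).
* Losses are a single fraction per country and class; no emission
  speciation or process-based storage modelling.
* Outlier handling is explicit (discard rules), never automatic.
* The anomaly screen for yield bases is advisory; final selection is a
  human decision recorded in configuration.
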