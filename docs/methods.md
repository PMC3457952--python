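# Model and methods

`volepom` is an individual-based model of field-vole (*Microtus agrestis*)
population dynamics on 1 m² raster landscapes, together with the
pattern-oriented testing harness used to calibrate it: pattern statistics
for four sets of published field patterns, a virtual-ecologist trapping
module, a sequential calibration engine, and a one-at-a-time sensitivity
analyzer. This note documents the model, its assumptions, the parameters
that matter, and the design choices made where the underlying description
left the design open.

## The world

The landscape is a raster of integer habitat codes (unmanaged grassland,
tussocky and low-yield pasture, set-aside, linear features, arable,
woodland, forest plantation, dispersal-only matrix, and impassable
non-habitat), 1 cell = 1 m². Connected same-class regions are labelled as
patches. Cell positions are cell centers, coordinates are 0-based
row-major, and all distances are Euclidean in meters.

Forage quality of a cell is the product of three terms:

* a per-class base quality (grassland highest at 0.68, woodland and arable
  lowest; the full table is `landscape.BASE_QUALITY`). These are package
  constants, not field measurements;
* the patch's **digestibility** `min(1, 0.7 + sqrt(g))`, where `g` is the
  fraction of standing biomass younger than 14 days. Biomass is kept as a
  daily cohort ledger per patch: on days with mean temperature at or above
  the growth threshold V14 = 3.552 °C a fixed increment is added, cohorts
  age out of the "new green" pool at 14 days, and standing biomass senesces
  at 1 %/day. During sustained growth digestibility saturates at 1.0; two
  weeks after growth stops it falls to the 0.7 floor. Drought effects are
  deliberately absent;
* a **within-class quality field**: a smoothed multiplicative random field
  (sd 0.12, 10 m correlation length, clipped to [0.3, 1.7]). Its role is
  seasonal: in summer virtually the whole sward clears the
  territory-quality threshold, while at the winter digestibility floor the
  poorer ~40 % of grassland falls below it, so the population contracts to
  the better swards. Without this heterogeneity winter carrying capacity
  is implausibly high and the seasonal density cycle collapses.

Weather is a daily series (temperature, precipitation). The synthetic
generator produces a sinusoidal annual profile with seeded daily noise;
the `finland_like` profile (mean 6.0 °C, amplitude 11.5) crosses the
growth threshold in spring roughly three weeks later than `denmark_like`
(8.5/8.5). The **breeding window** of a year opens on the first day D such
that days D−6…D all reach V14, floored at the earliest calendar date
V15 = 80, and closes for new conceptions at V11 = 230.

## The vole agents

Voles are individual agents with sex, age, position, natal position, an
assigned physiological lifespan (Normal(15, 3) months, 1 month = 30.44
days, truncated at 1 day), and optionally a circular territory (center +
radius). Females mature at V2 = 23 days, males at V1 = 30. The daily
schedule is: vegetation update; then each vole, in a freshly shuffled
order — mortality, aging, territory assessment and eviction, mating,
restlessness, birth, dispersal or within-range movement; then weaning;
then the predator step; then recording. One RNG stream drives everything,
so same-seed runs are bit-identical.

**Territories.** A prospective territory at a location is scanned from the
sex-specific minimum radius (8 m females, 9 m males) upward (to 8 and
23 m respectively). The forage criterion — mean cell quality × V3 ≥ 1
with V3 = 2.1 — is judged on the core range (the minimum radius) for both
sexes; larger radii only widen the search for mates. A radius is
acceptable if additionally the local occupant count stays below the
density threshold V13 = 4, scaled for males by the ratio of minimum
territory areas ((9/8)² → 5.06). Because counts are integers, the rounding
of the male threshold decides which sex is squeezed out first in crowded
seasons; settlement uses the floored value (5) while established holders
are evaluated against the unfloored one. This split keeps the binding
densities of the sexes nearly equal at settlement while letting holders of
both sexes ride out transient crowding, and it was the only variant of
the boundary that reproduced both the day-90 parity and the day-200
female bias of the population patterns (see Calibration below).

Daily, a territory holder re-checks quality (core radius) and crowding
(held radius); failing either, or being overlapped by more than 50 % (of
its own circle's area) by a same-sex holder at least V8 = 30 days older,
it loses the territory and becomes a disperser.

**Mating and reproduction.** A territorial adult female in the breeding
window conceives when at least one adult male's territory contains her
position, choosing the nearest male center (ties to the lower id).
Gestation is 21 days; litters are truncated-Poisson (mean 5.4, minimum 1);
pups stay at the nest (the mother's territory center) and become
independent agents at 14 days, sex assigned by a fair coin. Conception is
blocked during lactation, giving a 35-day birth interval. The mother's
death kills her unweaned litter.

**Movement.** Territory holders move daily to a uniform random point of
their range — females within their territory radius, males within an
18 m ranging radius (male home ranges exceed the defended core). These
positions are what the virtual traps sample. Dispersers move by a
correlated random walk (14 m/day budget) that mostly refuses to leave
forage-bearing habitat, and attempt to settle at each day's endpoint.

**Natal dispersal.** Weanlings born at crowded natal sites (count within
8 m at or above 0.35·V13) express, with probability 0.7, an obligate
disperser phenotype: for 5–10 days (drawn uniformly) they travel fast and
straight (30 m/day, small heading noise) without attempting to settle.
This density-dependent disperser/philopatric dimorphism is what produces
the observed natal-dispersal tail (13.8 % beyond two home-range diameters)
while most recruits settle within one home range.

**Mortality.** Each day a vole dies with the background probability
V10 = 0.0025; each day spent dispersing adds the independent hazard
V9 = 0.055 (multiplicative survival); age beyond the assigned lifespan is
certain death. The starvation-days concept is disabled (V16 = ∞).

**Male roving and infanticide.** The original model ties male behaviour to
females: a territorial male whose range overlaps no adult female abandons
it with daily probability V12 = 0.0505, and during the breeding window a
dispersing adult male only settles where an adult female lies within the
prospective radius. Beyond that, territorial adult males make excursions
beyond their territory (daily probability 0.63 in the breeding window,
reduced by the factor 0.135 for the rest of the growing season; reach
30 m). An excursion exposes the male to the dispersal hazard V9 and to
infanticide opportunities: an unweaned litter within 2 m is attacked with
probability V17 = 1.0 and destroyed with probability 1 − age/14. Male
roving is the engine of the summer male deficit (the 1:1.95 day-200 sex
ratio); its off-season tail sets how much of the deficit survives into
spring.

## Predators

Specialist predators (small mustelid-like agents) are enabled only for
the cycling scenarios; everywhere else their effect is part of V10, and a
guard refuses predator configurations for the other scenarios. A predator
kills up to 1 vole/day within its 40 m home range, counts a day
unsuccessful when fewer than 30 voles are within range, disperses ~60 m
(staying in habitat) after 4 unsuccessful days, and starves after 75.
Once per year, inside the reproduction window and with at least 40 voles
in range, it produces a litter of 6 that disperses to its own hunting
grounds. A spring immigration floor (1 predator) reconnects the local
guild to a regional pool after crash-phase extinctions, and the cycling
scenarios likewise admit 10 immigrant voles each spring — desk-scale
landscapes are far smaller than real ones and are not meaningfully closed.
The delayed numerical response (annual reproduction, slow starvation)
generates multi-annual cycles; landscape fragmentation desynchronizes
patches and damps the aggregate amplitude.

## The virtual ecologist

The trapping module reproduces the dispersal-study design: three 14 × 7
grids of traps at 7 m spacing with 30 m between grids, centered in a
500 × 400 m meadow bounded by forest. Daily, every vole within 1 m of a
trap is identified (nearest trap, lowest index on ties), recording trap
location, natal location, date, id, age and sex. Trapping is
detection-only: no behavioural capture effect and no retention.

Statistics are computed from the capture ledger exactly as from a field
notebook: philopatry (percent of adult inter-capture movements beyond two
home-range diameters, 90 m males / 70 m females), mean successive-capture
distance, mean per-individual maximum capture distance, and natal
dispersal — the distance from the natal site to the **first capture at
adult age**, restricted to voles born within the trap-array bounding box
dilated by one sex-specific home-range diameter. The adult-capture
definition matters: a juvenile capture at the nest would not measure
dispersal, which completes around maturity.

## Pattern statistics and targets

* Set 1 (homogeneous block, no predators): mean of daily females/males
  over day 90 ± 15 and day 200 ± 15 across post-burn-in years (a
  ratio-of-summed-counts variant is available); mean female count over
  day 200 ± 15 per hectare of grassland; age structure as proportions per
  age class (defaults 14–30, 31–60, 61–90, >90 days) at mid-month
  (the 15th) of May–September, scored as the mean over months of summed
  squared proportion differences, per sex.
* Set 2 (mosaic): seasonal mean densities over qualifying patches (>1 ha,
  except unmanaged grassland and linear features at ≥1000 m²), scored as
  the total absolute natural-log deviation against a user-supplied target
  table; observations in the "<9 voles/ha" lumped category score zero
  inside the category and ln(model/9) beyond it; pass mark 10.0 in total.
* Set 3: the trapping statistics above with the printed criteria
  (philopatry < 2 % per sex; successive and maximum distances within the
  published mean ± sd bands; natal fractions 13.8 ± 5 % far, 60 ± 10 %
  near).
* Set 4: cycle metrics over annual peak abundances — amplitude
  ln(max/min) (minimum clamped to one animal and flagged), period as mean
  local-maxima spacing, low phase as mean run length below the geometric
  mean. Regimes are classified by amplitude: ≥2.5 deep regular cycles,
  ≥1.5 intermediate, else weak fluctuations.

## Calibration

All seventeen registry parameters are held at their post-calibration
values. The constants the registry does not pin — litter size, gestation,
movement and dispersal scales, excursion rates, base qualities, quality
heterogeneity, predator magnitudes — were fitted with the package's own
sequential procedure: first the block-scenario patterns (sex ratios and
density), then the dispersal patterns with a re-check of the block
patterns after every change, then the cycling regimes. The mechanism
chain that the calibration forced into place is worth recording: the
day-200 female bias requires a breeding-season male mortality surplus
(roving); day-90 parity requires that surplus to fade over winter, partly
by its off-season decay and partly because the autumn cohort (born 1:1,
maturing after the roving season) dilutes the skew; the 75 females/ha
census requires winter range contraction (quality heterogeneity) to reset
spring density well below the crowding ceiling. Desk-scale fitted means
over 10–12 replicate seeds: day-90 ratio 0.98–1.00, day-200 ratio
1.93–1.96, female density 74–76/ha — deviations of the same order as the
original study's accepted fit (+2.1 %, −1.3 %, +0.4 %).

## Desk scales

The published protocols (10 × 10 km maps, 20–30 year runs, tens of
thousands of runs) are reproduced at reduced scale, recorded in every
scenario's `scale_factor`:

* block scenario: 200 m grassland block in an equal dispersal-only
  surround, 10 years, 5 burn-in, ≥10 replicates;
* trap meadow: the full 500 × 400 m meadow, 5 burn-in years + 2 sampled;
* cycling: one 12.25 ha patch in a 700 × 700 m matrix (50 years, 10
  burn-in); the 3-patch landscape is drawn at 500 m so patches couple
  weakly (intermediate regime); 16 patches at 700 m desynchronize fully;
* mosaic: 500 × 500 m random mosaic, 8 years.

## What the synthetic data do and do not show

The generators emulate the *structure* of the study conditions —
habitat-class geometry, northern vs. maritime weather, trap layout — not
their particulars: real GIS maps, real weather series and the
supplementary numeric target tables (age structure, habitat–season
densities) are consumed as user-supplied inputs when available, and the
corresponding fits are exercised property-based otherwise (zero iff
exact, monotone under perturbation). Passing the desk-scale tests shows
the mechanisms jointly reproduce the printed patterns under synthetic
conditions; it does not validate the model against new field data, nor
calibrate the unmeasured constants beyond the patterns used.

## Numerical choices and degenerate inputs

Integer counts make density thresholds discrete; the settlement/holder
rounding split above is the documented resolution. Ratio statistics skip
days with zero males and raise only if no qualifying day has males.
Amplitude on a series touching zero clamps the minimum to one animal and
flags it. Mid-month means day 15. Tie-breaks are deterministic (nearest,
then lowest id/index). Agent capacity is pre-allocated (600/habitat-ha);
exhaustion is counted, never silent. The daily processing order is
re-shuffled every day from the run RNG to avoid order artifacts; the
kernel RNG stream is process-global, so interleaving two simulations'
`step_day` calls within one process interleaves their draws (replicates
run sequentially are unaffected).

## Known limitations

Food is not depletable; drought and snow are absent; trapping has no
behavioural effect; predator internals are deliberately minimal
(no predator-predator interaction); the within-class quality field, the
male excursion rates, the disperser phenotype and the immigration floors
are calibrated constructs standing in for processes the available
patterns cannot identify separately. The hill-climbing calibration is
greedy and sequential; it finds a defensible optimum, not a posterior.
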