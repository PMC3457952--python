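# volepom

An individual-based model of field-vole (*Microtus agrestis*) population
dynamics on 1 m² raster landscapes, with the pattern-oriented modelling
(POM) harness used to test and calibrate it.

Field-vole populations show a family of robust, well-documented patterns:
near-parity sex ratios in spring that shift to roughly 1:1.95 males:females
by mid-summer; peak breeding-season densities around 75 females per
hectare in prime habitat; strong adult philopatry (fewer than 2 % of
movements beyond two home-range diameters) alongside long-tailed natal
dispersal; and, where specialist predators dominate, multi-annual
population cycles with ln(max N/min N) amplitudes around 3 and a period
near 5 years. `volepom` is for modellers who want a mechanistic,
agent-level simulation that reproduces these patterns *simultaneously* —
and a harness that measures how well it does, the way a field ecologist
would measure it.

## The model in brief

Voles live on a raster of habitat classes. Each day, every vole (in
shuffled order) faces mortality (background hazard V10 = 0.0025/day, an
added hazard V9 = 0.055 per dispersal day, a physiological lifespan of
15 ± 3 months), re-assesses its circular territory (mean forage quality ×
V3 ≥ 1, local crowding below the scaled threshold V13, eviction by a
sufficiently older same-sex neighbour at >50 % overlap), mates (nearest
overlapping male), breeds inside a weather-driven window (opened by seven
consecutive days at or above V14 = 3.552 °C, never before day 80, closed
at day 230), and moves — within its range, or dispersing in search of a
vacancy. Forage quality follows grass digestibility,
`min(1, 0.7 + sqrt(new-green fraction))`. Offspring wean at 14 days and
enter the world as agents. Roving males commit infanticide on unweaned
litters. Optional specialist predators with a delayed numerical response
generate population cycles on fragmented landscapes.

The POM harness provides the four pattern-set protocols (population
structure in a homogeneous block; densities across habitats on a mosaic;
a virtual live-trapping grid with mark–release–recapture statistics;
cycling regimes), a sequential calibration engine with hill climbing and a
forbidden-set rule, and a one-at-a-time ±80 % sensitivity sweep. The daily
scheduler is compiled with numba; a 4 ha scenario runs a simulated decade
in a few seconds.

## Worked example

Simulate the homogeneous high-quality block (200 m grassland in an equal
dispersal-only surround) for ten years and evaluate the population
patterns over the last five:

```python
from volepom import VoleParams, generate_landscape, sex_ratio, female_density
from volepom.sim import Simulation
from volepom.landscape import HabitatClass

grid = generate_landscape("homogeneous_block", dims=200)
sim = Simulation(grid, VoleParams(), years=10, seed=1)
result = sim.run()

area = grid.area_ha(HabitatClass.GRASSLAND_UNMANAGED)
print("sex ratio day 90:  %.3f females/male" % sex_ratio(result.counts, 90, 15, burn_in_years=5))
print("sex ratio day 200: %.3f females/male" % sex_ratio(result.counts, 200, 15, burn_in_years=5))
print("female density:    %.1f per ha" % female_density(result.counts, area, 200, 15, burn_in_years=5))
```

prints (seed 1):

```
sex ratio day 90:  1.050 females/male
sex ratio day 200: 2.023 females/male
female density:    65.9 per ha
```

One seed is one stochastic replicate: day 90 sits near parity, day 200
near the 1:1.95 summer female bias, and the census near 75 females/ha.
The fitting criteria are evaluated on means over at least ten replicates
(`volepom.engine.run_replicates`), where these statistics land within a
few percent of the targets — single seeds scatter around them, which is
why the calibration protocol demands replication.

The command line exposes the same machinery:

```bash
volepom simulate --scenario set1_block --replicates 10 --seed 0
volepom patterns --scenario set1_block --replicates 10
volepom genmap --kind trap_meadow --out meadow.asc
volepom gendata --out example_bundle     # map + weather + params bundle
```

## Layout

| module | contents |
| --- | --- |
| `volepom.landscape` | habitat raster, patches, vegetation/digestibility, breeding window, scenario map generators |
| `volepom.params` | the V1–V17 parameter registry and auxiliary life-history constants |
| `volepom.abm` | the per-vole behavioural rules, documented and unit-testable |
| `volepom._kernel` / `volepom.sim` | the compiled daily scheduler and the simulation driver |
| `volepom.predation` | specialist predators with delayed numerical response |
| `volepom.trapping` | virtual trapping grids and mark–release–recapture statistics |
| `volepom.patterns` | pattern statistics, targets, and pass/fail evaluation |
| `volepom.engine` | scenarios, replicate manager, sequential calibration, sensitivity |
| `volepom.io` / `volepom.cli` | rasters (ESRI ASCII), weather CSV, manifests, command line |

`docs/methods.md` documents the model, its assumptions, every calibrated
constant, and the known limitations.
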