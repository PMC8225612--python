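# ondatra

Agent-based simulation of a muskrat (*Ondatra zibethicus*) metapopulation on
an annually changing floodplain, for spatial ecologists studying how flood
pulses and long-term drying drive eruptive population dynamics, riparian
corridor dispersal and source–sink structure in wetland mammals.

## The model in brief

Female agents live on a hexagonal lattice (cell width 60 m, area
(√3/2)·w² ≈ 0.31 ha ≈ one home range).  Each year every individual:

* in flood years, is first swept a log-normal distance
  (mode 10 cells = 600 m, median 100 cells = 6 km; μ = ln median,
  σ = √ln(median/mode)) along a zero-resistance walk;
* searches its local surroundings (≤500 cells ≈ 1.6 km²) for a free
  settleable hexagon — the spring shuffle;
* on failure performs a constrained random walk over the year's dispersal
  surface, accruing resistance 10 − score per cell entered (land 10, water
  0) until the threshold 500 (≈3 km overland) or 1000 steps (≈60 km through
  water); wet cells attract with weight 5:1 and headings persist with 50%
  autocorrelation over a 3-step window;
* reproduces if settled (Poisson recruits scaled by local suitability,
  ≤15), then survives age-specifically (s₁ = 0.40, s₂ = 0.10, max age 3).

Habitat is the shoreline fringe: annual land/water rasters are classified
into land/shoreline/water, and per-hexagon dispersal (0–10) and suitability
(shoreline fraction, 0–1) surfaces are built by area-weighted resampling.
Births and deaths feed per-hexagon ledgers and a full pedigree, from which
the package maps productivity (births − deaths per 0.28 km² super-hexagon),
dispersal flux (distinct dispersers crossing a cell), source/sink areal
extent, and within- vs between-site first-order-relative tallies from
virtual trapping.  A parametric generator builds multi-year synthetic
floodplain atlases (river corridor, lakes, isolated ponds, flood expansion
and drying) so everything is testable without satellite data.

## Worked example

```python
import numpy as np
from ondatra import (DeltaScenario, DemographyParams, FloodKernel, WalkParams,
                     generate_atlas, place_sites)
from ondatra.experiment import run_experiment
from ondatra.reports import first_order_tally, virtual_sample

scenario = DeltaScenario(n_rows=60, n_per_row=60, n_years=12, flood_years=(4,),
                         n_lakes=3, n_isolated=1, lake_radius_px=(4, 6),
                         isolated_radius_px=(3, 4), seed=11)
atlas = generate_atlas(scenario)
n0 = int(0.5 * atlas.settleable(0).sum())
result = run_experiment(atlas, DemographyParams(), WalkParams(), FloodKernel(),
                        n_realizations=5, base_seed=0, initial_females=n0)
print(result.median_series().to_string(index=False))
```

prints the median census across the five realizations (`total` is twice the
modelled female count, following even breeding sex ratios):

```
 year  females  total
    0    357.0  714.0
    1    244.0  488.0
    2    304.0  608.0
    3    257.0  514.0
    4    772.0 1544.0
    5    435.0  870.0
    6    551.0 1102.0
    ...
   11    433.0  866.0
```

The population triples in the flood year (year 4), when the expanding marsh
mosaic opens new habitat and flood transport redistributes colonists, then
declines through the drying years — the eruption/die-off cycle.  Continuing
with virtual trapping at two lake sites in the flood year:

```python
sites = place_sites(atlas, 2, seed=0)
r = result.realizations[0]
picked = virtual_sample(r.homes_by_year[4], sites, 10**9, np.random.default_rng(0))
tally = first_order_tally(picked, r.mother_of, year=4)
print(tally.pairs_within, "within,", tally.pairs_between, "between")
# 1109 within, 4 between
```

Most mother–daughter and sibling pairs still live at the same lake, but the
flood has carried a few families across sites — the genetic fingerprint of
flood-borne mixing.

A `ondatra` command-line interface wraps the same pipeline
(`generate`, `run`, `report`, `sample`); see `ondatra --help`.

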