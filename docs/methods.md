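# Methods

## The model

`ondatra` simulates the female segment of a muskrat (*Ondatra zibethicus*)
metapopulation on a floodplain whose habitat is redrawn every year.  The
landscape is a lattice of pointy-top hexagons in offset rows ("odd-r"); the
cell width (flat-to-flat, default 60 m) equals the centre spacing within a
row, and cell area is (√3/2)·width² ≈ 0.31 ha — roughly one muskrat home
range, so at the default occupancy cap each settleable hexagon hosts at most
one breeding female.

Each year of the annual cycle runs, in order:

1. **Flood transport** (flood years only).  Every individual is displaced
   along a random walk on a constant score-10 surface (zero resistance) whose
   length is drawn from a log-normal kernel specified by its mode (10 cells,
   600 m) and median (100 cells, 6 km): μ = ln(median),
   σ = √ln(median/mode).  Half of the flood-borne animals therefore stay
   within 6 km of home while a tail is carried tens of kilometres.
2. **The spring shuffle.**  Every individual searches its surroundings
   nearest-first, up to 500 hexagons (≈1.6 km²), and settles in the first
   free settleable cell; ties within a distance ring are broken by the
   realization's RNG.
3. **Long-range dispersal.**  Individuals that fail locally walk the year's
   dispersal surface.  Each cell entered adds `10 − score` to a cumulative
   resistance (land 10, open water 0, shoreline fringe in between); the walk
   stops at resistance 500 (50 land cells ≈ 3 km overland) or at 1000 steps
   (≈60 km through open water).  Steps prefer wet cells — neighbours scoring
   in [2, 10] carry 5× the weight of neighbours in [0, 1], with a linear ramp
   between — and with probability 0.5 a step instead follows the mean heading
   of the last 3 steps.  After the walk the local search is repeated; a
   second failure removes the individual (death or emigration out of the
   modelled area), recorded as a death at the walk terminus so that sink maps
   capture dispersal mortality.
4. **Reproduction.**  Each settled female recruits
   `min(Poisson(λ·suitability), 15)` daughters (λ = 6), born at her cell;
   recruits must settle through the same local search or are removed.
   First-year mortality is folded into the recruitment rate, so age-0
   recruits skip the survival draw.
5. **Survival** by age: s₁ = 0.40, s₂ = 0.10, hard maximum age 3, giving
   P(reach age 3) = 0.04, consistent with field longevity (<5% reach three
   winters).  A config validator enforces this bound; it can be switched off
   for idealized desk scenarios (e.g. immortal agents in conservation
   checks).
6. **Ageing.**

Every birth and death is logged per hexagon (the productivity ledger) and in
a complete pedigree (id, mother, birth/death year and cell).  The census
convention reports total population as twice the living female count.

## Landscape surfaces

A year enters as a binary land/water raster.  The shoreline — a one-pixel
band on both sides of the land/water interface (4-neighbourhood) — is the
limit of an edge-detection pass on binary input, so no gradient filter is
needed.  Two per-hexagon surfaces follow by area-weighted resampling
(regular sub-sampling, 16 sub-points per pixel, validated against a
Monte-Carlo area oracle): the dispersal surface (water/shoreline pixels 10,
land 0) and the habitat surface (shoreline-pixel area fraction, in [0, 1]).
Open water is traversable but not settleable; a hexagon is settleable when
its suitability reaches `settle_threshold` (default 0.1).

Source–sink reporting aggregates births − deaths over super-hexagons of
radius 5 (91 unit cells, 0.28 km²); blocks clipped by the grid boundary keep
their actual area.  The source/sink extent statistic divides the area of
blocks with nonzero productivity by the area of blocks containing any
settleable habitat — the delta, not the open water/land matrix.  Dispersal
flux counts distinct individuals whose walk crossed a cell in a year
(a step-visit mode exists behind a flag); across realizations population
series aggregate by the median and maps by the mean.

## The synthetic floodplain generator

The generator emulates the study conditions the simulator needs without any
satellite input: a wiggly river corridor strung with lakes (discs), plus
isolated ponds off the network.  A smooth synthetic bathymetry (Gaussian-
filtered noise, deepening toward existing water) orders all wetting and
drying.  Flood years grow the water mask outward, deepest ground first,
until the area has multiplied by the expansion factor (default 2.0), but a
fixed 35% of raised-ground pixels never flood — newly flooded zones
therefore come up as a water/land mosaic, the marsh fringe that constitutes
muskrat habitat, so the settleable area jumps at a flood.  Drying years
remove the shallowest exposed water at the drying rate (3%/yr), emptying the
marsh mosaics first and contracting habitat, while a thin perennial core
(river centreline, lake centres) stands in for permanent channels.  Isolated
ponds sit in shallow perched basins (a local depth offset) with no perennial
core: they are the first to dry and the last to reflood, which produces the
site-dependent local extinction the model is meant to exhibit.  Everything
is deterministic given the scenario seed.

Deliberately not emulated: hydrodynamics, sediment, vegetation succession
and herbivory feedbacks, multi-sensor imagery artefacts, and any calibration
to the real delta's geometry.  Passing desk tests therefore demonstrates the
mechanisms (flood-driven eruption, corridor dispersal, flood mixing,
source–sink turnover), not predictions for a specific real floodplain.

Sampling sites are placed by k-means clustering of hexagons settleable in at
least half the years; each site is the largest disc around a cluster
centroid that cannot touch a neighbouring site (capped at a 1.5 km trapping
radius), labelled A, B, … west to east.  Virtual trapping samples settled
residents per site uniformly without replacement; pairs are classified
first-order (mother–daughter or same-mother siblings) from the true
pedigree, split within- vs between-site, with per-mil rates over the
possible within/between pairs.

## Desk-scale study conditions

The flood-response scenario used by the test suite runs a 200×200-hexagon
grid (12 km × 10.4 km) for 47 years with floods in years 5 and 20, ten
realizations, founders filling half the initial settleable capacity.  These
sizes keep a full run to a few minutes while leaving several hundred
settleable hexagons per water body.  Relatedness checks census every site
resident rather than a 30-animal subsample: pedigree truth is only visible
for pairs actually sampled, and at desk-scale populations sparse subsamples
almost never contain both members of a separated family.

## Numerical and design notes

* One RNG stream (`numpy` PCG64) per realization, seeded
  `base_seed + realization_index`; every stochastic operation draws from it
  in the documented event order, so any single realization reproduces in
  isolation.
* Offset-rectangle hexagonal grids have corner cells with as few as two
  in-bounds neighbours; walks simply cannot leave the grid, and emigration
  is represented by removal after failed settlement, not by off-grid travel.
* The super-hexagon tessellation assigns each cell to the unique block
  centre within hex distance r on the lattice generated by the axial basis
  (2r+1, −r), (r, r+1); determinant 3r²+3r+1 guarantees an exact partition.
* Scores in the open interval (1, 2) — between the repulsion and attraction
  ranges — take linearly interpolated step weights to avoid a
  discontinuity.
* Revisited cells re-incur resistance: the penalty accrues per step of
  travel, not per unique cell.
* A flood-year walk whose kernel draw exceeds what the grid allows simply
  truncates at its realized path; no re-draw.
* Raster I/O uses ESRI ASCII grids; hexagon surfaces serialize as dense
  text arrays with a JSON sidecar carrying the grid definition.

## Known limitations

* No males, no within-year dynamics, no disease or harvest; relatedness is
  pedigree truth, not a genotype-based estimate, so genotyping error and
  marker resolution are out of scope.
* The habitat model grades suitability only by shoreline fraction; real
  fringe quality (vegetation type, water depth) is not distinguished.
* Flood transport applies to every individual in a flood year; partial
  exposure would need the per-individual subsampling flag.
* At full delta scale (3×10⁶ cells, ~6×10⁴ founders) a realization is
  computationally heavy in pure Python; the desk scenario is the supported
  regime.
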