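"""Annual agent scheduler: settlement, dispersal, demography, pedigree.

Female muskrat agents live on the hexagon lattice, one breeding female per
settleable cell (configurable cap).  Each simulated year runs, in order:

1. flood transport (flood years only): every individual is carried along a
   zero-resistance walk of kernel-drawn length and relocated to its terminus;
2. the spring shuffle: every individual searches its local surroundings
   (nearest-first, up to 500 cells ≈ 1.6 km²) for a free settleable cell;
3. individuals that fail locally make one constrained long-range walk on the
   year's dispersal surface and search again from the terminus; a second
   failure removes them (death or emigration), recorded at the terminus;
4. settled females recruit daughters (Poisson with suitability-scaled rate,
   capped at 15); recruits are recorded as births at the mother's cell and
   must settle locally themselves or are removed;
5. age-specific survival; 6. survivors age one year.

Every birth and death is logged to a per-hexagon ledger (the productivity
input) and to the pedigree (the relatedness truth).  The census convention
reports total population as twice the living female count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hexgrid import HexGrid, disk_offsets
from .landscape import AnnualAtlas, make_flood_surface
from .movement import DispersalContext, FloodKernel, WalkParams, flood_walk
from .reports import FOUNDER, accumulate_flux

UNSETTLED = -1

#: Initial female count configured for the real-delta scenario (scaled from an
#: observed house count at a single well-surveyed lake).
DELTA_INITIAL_FEMALES = 59_701


def females_from_houses(houses: int, females_per_house: float = 2.5) -> int:
    """Initial female estimate at a surveyed lake from its house count."""
    return round(houses * females_per_house)


def scale_to_delta(lake_females: float, lake_habitat_km2: float,
                   delta_habitat_km2: float) -> int:
    """Scale a single-lake female estimate by its share of critical habitat."""
    return round(lake_females / (lake_habitat_km2 / delta_habitat_km2))


@dataclass(frozen=True)
class DemographyParams:
    max_offspring: int = 15       # hard cap on female recruits per female-year
    litter_rate: float = 6.0      # Poisson rate scale; λ = rate × suitability
    survival: tuple[float, ...] = (0.40, 0.10)   # by age (1, 2, ...)
    max_age: int = 3
    occupancy_cap: int = 1        # breeding females per settleable hexagon
    exploration_cells: int = 500  # local-search extent of the spring shuffle
    #: muskrat in the field rarely outlive two winters; realistic schedules
    #: keep P(reach max_age) < 5%.  Disable for idealized desk scenarios
    #: (e.g. immortal agents in conservation checks).
    validate_schedule: bool = True

    def __post_init__(self) -> None:
        errors = self.validate()
        if errors:
            raise ValueError("; ".join(errors))

    def validate(self) -> list[str]:
        errors = []
        if not all(0.0 <= s <= 1.0 for s in self.survival):
            errors.append("survival entries must be probabilities")
        p_old = math.prod(self.survival[: self.max_age - 1])
        if self.validate_schedule and p_old >= 0.05:
            errors.append(
                f"survival schedule gives P(reach age {self.max_age}) = {p_old:.3f} >= 0.05"
            )
        if self.max_offspring < 0 or self.litter_rate < 0:
            errors.append("recruitment parameters must be non-negative")
        if self.occupancy_cap < 1:
            errors.append("occupancy cap must be >= 1")
        return errors

    def survival_prob(self, age: int) -> float:
        if age == 0:
            return 1.0            # first-year mortality is folded into recruitment
        if age >= self.max_age:
            return 0.0
        if age - 1 < len(self.survival):
            return self.survival[age - 1]
        return 0.0


@dataclass
class Individual:
    id: int
    age: int
    home: int                     # flat cell index, or UNSETTLED
    loc: int                      # current position (walk terminus before settling)
    mother_id: int = FOUNDER
    alive: bool = True


@dataclass
class PedigreeRecord:
    mother_id: int
    birth_year: int
    birth_cell: int
    death_year: int | None = None
    death_cell: int | None = None


@dataclass
class PopulationState:
    grid: HexGrid
    year: int
    individuals: dict[int, Individual] = field(default_factory=dict)
    occupancy: np.ndarray = None
    pedigree: dict[int, PedigreeRecord] = field(default_factory=dict)
    next_id: int = 0

    def __post_init__(self) -> None:
        if self.occupancy is None:
            self.occupancy = np.zeros(self.grid.n_cells, dtype=np.int32)

    def homes(self) -> dict[int, int]:
        return {i.id: i.home for i in self.individuals.values() if i.alive}

    def mother_of(self) -> dict[int, int]:
        return {pid: rec.mother_id for pid, rec in self.pedigree.items()}


def census(state: PopulationState) -> dict[str, int]:
    """Living females, and total population as twice the female count."""
    females = sum(1 for i in state.individuals.values() if i.alive)
    return {"females": females, "total": 2 * females}


# ---------------------------------------------------------------------------
# Exploration (the spring shuffle's local search)


class Explorer:
    """Nearest-first scan of up to ``max_cells`` hexagons around a start cell.

    Rings of increasing hex distance are scanned in order; the first ring
    holding any free settleable cell wins, ties within the ring broken by the
    realization's RNG.  The outermost ring is truncated to land exactly on
    the cell budget.

    The scan is one vectorised pass: ring offsets are precomputed as
    (drow, dcol) displacements, which on the offset layout depend only on the
    start row's parity.
    """

    def __init__(self, grid: HexGrid, max_cells: int = 500):
        self.grid = grid
        self.max_cells = max_cells
        radius = 0
        while 1 + 3 * radius * (radius + 1) < max_cells:
            radius += 1
        rings = disk_offsets(radius)
        flat: list[tuple[int, int, int]] = []   # (ring, dq, dr)
        total = 0
        for d, ring in enumerate(rings):
            take = min(len(ring), max_cells - total)
            flat.extend((d, dq, dr) for dq, dr in sorted(ring)[:take])
            total += take
            if total >= max_cells:
                break
        self.ring_id = np.array([f[0] for f in flat])
        dq = np.array([f[1] for f in flat])
        dr = np.array([f[2] for f in flat])
        self.dr = dr
        # dcol depends only on (dq, dr, start-row parity)
        self.dc = []
        for row0 in (10, 11):   # representative even / odd start rows
            q0 = -(row0 - (row0 & 1)) // 2
            rr = row0 + dr
            self.dc.append((q0 + dq) + (rr - (rr & 1)) // 2 - 0)
        # the expressions above give cc for col0 = 0

    def explore(self, start: int, settleable: np.ndarray, occupancy: np.ndarray,
                cap: int, rng: np.random.Generator) -> int | None:
        g = self.grid
        row, col = divmod(start, g.n_per_row)
        rr = row + self.dr
        cc = col + self.dc[row & 1]
        ok = (rr >= 0) & (rr < g.n_rows) & (cc >= 0) & (cc < g.n_per_row)
        cells = rr[ok] * g.n_per_row + cc[ok]
        free = settleable[cells] & (occupancy[cells] < cap)
        if not free.any():
            return None
        cells = cells[free]
        rings = self.ring_id[ok][free]
        best = cells[rings == rings.min()]
        if best.size == 1:
            return int(best[0])
        return int(best[int(rng.integers(best.size))])


# ---------------------------------------------------------------------------
# Initialization


def initialize_population(grid: HexGrid, habitat: np.ndarray, n_females: int,
                          params: DemographyParams, rng: np.random.Generator,
                          settle_threshold: float = 0.1,
                          start_year: int = 0) -> PopulationState:
    """Place founders in settleable cells with probability ∝ suitability."""
    state = PopulationState(grid, year=start_year)
    if n_females == 0:
        return state
    settleable = np.flatnonzero(habitat >= settle_threshold)
    capacity = settleable.size * params.occupancy_cap
    if n_females > capacity:
        raise ValueError(
            f"initial population {n_females} exceeds settleable capacity {capacity}"
        )
    slots = np.repeat(settleable, params.occupancy_cap)
    weights = habitat[slots]
    p = weights / weights.sum()
    chosen = rng.choice(slots, size=n_females, replace=False, p=p)
    for cell in chosen:
        cell = int(cell)
        ind = Individual(state.next_id, age=1, home=cell, loc=cell)
        state.individuals[ind.id] = ind
        state.occupancy[cell] += 1
        state.pedigree[ind.id] = PedigreeRecord(FOUNDER, start_year - 1, cell)
        state.next_id += 1
    return state


def explore_and_settle(ind: Individual, state: PopulationState,
                       settleable: np.ndarray, params: DemographyParams,
                       rng: np.random.Generator,
                       explorer: Explorer | None = None) -> bool:
    """One local-search attempt; settles the individual on success."""
    explorer = explorer or Explorer(state.grid, params.exploration_cells)
    cell = explorer.explore(ind.loc, settleable, state.occupancy,
                            params.occupancy_cap, rng)
    if cell is None:
        return False
    ind.home = cell
    ind.loc = cell
    state.occupancy[cell] += 1
    return True


# ---------------------------------------------------------------------------
# The annual step


@dataclass
class YearRecord:
    year: int
    births: np.ndarray            # per-hexagon birth tally
    deaths: np.ndarray            # per-hexagon death tally (removals included)
    flux: np.ndarray              # per-hexagon distinct-disperser tally
    females: int
    total: int
    n_flood_walks: int = 0
    n_long_walks: int = 0


class Simulation:
    """Drives one realization of the annual cycle over an atlas."""

    def __init__(self, atlas: AnnualAtlas, demography: DemographyParams,
                 walk_params: WalkParams, kernel: FloodKernel,
                 rng: np.random.Generator,
                 context_cache: dict | None = None):
        self.atlas = atlas
        self.demography = demography
        self.walk_params = walk_params
        self.kernel = kernel
        self.rng = rng
        self.explorer = Explorer(atlas.grid, demography.exploration_cells)
        # dispersal contexts are pure functions of (grid, surface, params);
        # a shared cache lets realizations of one experiment reuse them
        self._ctx_cache = context_cache if context_cache is not None else {}
        if "flood" not in self._ctx_cache:
            self._ctx_cache["flood"] = DispersalContext(
                atlas.grid, make_flood_surface(atlas.grid), walk_params
            )
        self._flood_ctx = self._ctx_cache["flood"]

    def _dispersal_context(self, year: int) -> DispersalContext:
        if year not in self._ctx_cache:
            self._ctx_cache[year] = DispersalContext(
                self.atlas.grid, self.atlas.years[year].dispersal, self.walk_params
            )
        return self._ctx_cache[year]

    def annual_step(self, state: PopulationState, year: int) -> YearRecord:
        if year not in self.atlas.years:
            raise ValueError(f"atlas has no year {year}")
        atlas_year = self.atlas.years[year]
        settleable = self.atlas.settleable(year)
        habitat = atlas_year.habitat
        grid = state.grid
        rng = self.rng
        demo = self.demography
        births = np.zeros(grid.n_cells, dtype=np.int64)
        deaths = np.zeros(grid.n_cells, dtype=np.int64)
        flux = np.zeros(grid.n_cells, dtype=np.int64)
        n_flood = n_long = 0

        alive_ids = sorted(i for i, ind in state.individuals.items() if ind.alive)
        order = [alive_ids[k] for k in rng.permutation(len(alive_ids))]

        # everyone vacates their home range for the spring shuffle
        state.occupancy[:] = 0
        for i in alive_ids:
            ind = state.individuals[i]
            ind.loc = ind.home if ind.home != UNSETTLED else ind.loc
            ind.home = UNSETTLED

        # (1) flood transport
        if atlas_year.flood:
            for i in order:
                ind = state.individuals[i]
                out = flood_walk(self._flood_ctx, ind.loc, self.kernel, rng)
                accumulate_flux(flux, out)
                ind.loc = out.terminal
                n_flood += 1

        # (2) spring shuffle + (3) long-range dispersal on failure
        disp_ctx = self._dispersal_context(year)
        for i in order:
            ind = state.individuals[i]
            if explore_and_settle(ind, state, settleable, demo, rng, self.explorer):
                continue
            out = disp_ctx.walk(ind.loc, rng)
            accumulate_flux(flux, out)
            ind.loc = out.terminal
            n_long += 1
            if explore_and_settle(ind, state, settleable, demo, rng, self.explorer):
                continue
            # failed twice: death or emigration, recorded at the walk terminus
            self._record_death(state, ind, deaths, year, ind.loc, settled=False)

        # (4) reproduction; recruits settle locally or are removed
        mothers = [i for i in order if i in state.individuals
                   and state.individuals[i].alive]
        for i in mothers:
            mother = state.individuals[i]
            lam = demo.litter_rate * habitat[mother.home]
            n_recruits = min(int(rng.poisson(lam)), demo.max_offspring)
            for _ in range(n_recruits):
                rid = state.next_id
                state.next_id += 1
                births[mother.home] += 1
                recruit = Individual(rid, age=0, home=UNSETTLED,
                                     loc=mother.home, mother_id=mother.id)
                state.pedigree[rid] = PedigreeRecord(mother.id, year, mother.home)
                if explore_and_settle(recruit, state, settleable, demo, rng,
                                      self.explorer):
                    state.individuals[rid] = recruit
                else:
                    rec = state.pedigree[rid]
                    rec.death_year = year
                    rec.death_cell = mother.home
                    deaths[mother.home] += 1

        # (5) survival, (6) ageing
        for i in sorted(k for k, ind in state.individuals.items() if ind.alive):
            ind = state.individuals[i]
            p = demo.survival_prob(ind.age)
            survives = p >= 1.0 or (p > 0.0 and rng.random() < p)
            if not survives:
                self._record_death(state, ind, deaths, year, ind.home, settled=True)
            else:
                ind.age += 1

        state.year = year
        c = census(state)
        return YearRecord(year, births, deaths, flux, c["females"], c["total"],
                          n_flood, n_long)

    @staticmethod
    def _record_death(state: PopulationState, ind: Individual,
                      deaths: np.ndarray, year: int, cell: int,
                      settled: bool) -> None:
        deaths[cell] += 1
        rec = state.pedigree[ind.id]
        rec.death_year = year
        rec.death_cell = cell
        if settled and ind.home != UNSETTLED:
            state.occupancy[ind.home] -= 1
        ind.alive = False
        del state.individuals[ind.id]
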