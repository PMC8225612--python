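"""Multi-realization experiment orchestration.

One *realization* is a full pass of the annual cycle over the atlas with its
own RNG stream, seeded ``base_seed + realization_index``; re-running any
single realization in isolation reproduces it exactly.  Across realizations
the population series is aggregated by the median and the flux/productivity
maps by the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import AnnualAtlas
from .movement import FloodKernel, WalkParams
from .population import (
    DemographyParams,
    PopulationState,
    Simulation,
    YearRecord,
    initialize_population,
)


@dataclass
class RealizationResult:
    index: int
    seed: int
    census: pd.DataFrame                      # year, females, total, births, deaths
    homes_by_year: dict[int, dict[int, int]]  # year -> {id: home cell}
    mother_of: dict[int, int]
    pedigree: dict                            # id -> PedigreeRecord
    final_state: PopulationState


@dataclass
class ExperimentResult:
    atlas: AnnualAtlas
    realizations: list[RealizationResult]
    flux_sum: dict[int, np.ndarray] = field(default_factory=dict)
    births_sum: dict[int, np.ndarray] = field(default_factory=dict)
    deaths_sum: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_realizations(self) -> int:
        return len(self.realizations)

    def census_table(self) -> pd.DataFrame:
        frames = []
        for r in self.realizations:
            df = r.census.copy()
            df.insert(0, "realization", r.index)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def median_series(self) -> pd.DataFrame:
        """Per-year median female and total population across realizations."""
        t = self.census_table()
        med = t.groupby("year")[["females", "total"]].median().reset_index()
        return med

    def mean_flux(self, year: int) -> np.ndarray:
        return self.flux_sum[year] / self.n_realizations

    def mean_births_deaths(self, year: int) -> tuple[np.ndarray, np.ndarray]:
        n = self.n_realizations
        return self.births_sum[year] / n, self.deaths_sum[year] / n


def run_realization(
    atlas: AnnualAtlas,
    demography: DemographyParams,
    walk_params: WalkParams,
    kernel: FloodKernel,
    seed: int,
    initial_females: int,
    index: int = 0,
    on_year: "callable | None" = None,
    context_cache: dict | None = None,
) -> RealizationResult:
    """One full realization; ``on_year(record)`` sees every YearRecord."""
    rng = np.random.default_rng(seed)
    years = atlas.year_list()
    first = years[0]
    state = initialize_population(
        atlas.grid, atlas.years[first].habitat, initial_females, demography, rng,
        settle_threshold=atlas.settle_threshold, start_year=first - 1,
    )
    sim = Simulation(atlas, demography, walk_params, kernel, rng,
                     context_cache=context_cache)
    rows = []
    homes_by_year: dict[int, dict[int, int]] = {}
    for year in years:
        rec = sim.annual_step(state, year)
        rows.append(
            {
                "year": year,
                "females": rec.females,
                "total": rec.total,
                "births": int(rec.births.sum()),
                "deaths": int(rec.deaths.sum()),
            }
        )
        homes_by_year[year] = state.homes()
        if on_year is not None:
            on_year(rec)
    census = pd.DataFrame(rows)
    return RealizationResult(
        index=index,
        seed=seed,
        census=census,
        homes_by_year=homes_by_year,
        mother_of=state.mother_of(),
        pedigree=state.pedigree,
        final_state=state,
    )


def run_experiment(
    atlas: AnnualAtlas,
    demography: DemographyParams,
    walk_params: WalkParams,
    kernel: FloodKernel,
    n_realizations: int,
    base_seed: int,
    initial_females: int,
) -> ExperimentResult:
    """Run ``n_realizations`` independent realizations and aggregate maps."""
    result = ExperimentResult(atlas, [])
    n_cells = atlas.grid.n_cells
    for year in atlas.year_list():
        result.flux_sum[year] = np.zeros(n_cells, dtype=np.float64)
        result.births_sum[year] = np.zeros(n_cells, dtype=np.float64)
        result.deaths_sum[year] = np.zeros(n_cells, dtype=np.float64)

    def on_year(rec: YearRecord) -> None:
        result.flux_sum[rec.year] += rec.flux
        result.births_sum[rec.year] += rec.births
        result.deaths_sum[rec.year] += rec.deaths

    cache: dict = {}
    for i in range(n_realizations):
        r = run_realization(
            atlas, demography, walk_params, kernel,
            seed=base_seed + i, initial_females=initial_females,
            index=i, on_year=on_year, context_cache=cache,
        )
        result.realizations.append(r)
    return result


def pedigree_table(realization: RealizationResult) -> pd.DataFrame:
    rows = []
    for pid, rec in realization.pedigree.items():
        rows.append(
            {
                "id": pid,
                "mother_id": rec.mother_id,
                "birth_year": rec.birth_year,
                "birth_cell": rec.birth_cell,
                "death_year": rec.death_year if rec.death_year is not None else -1,
                "death_cell": rec.death_cell if rec.death_cell is not None else -1,
            }
        )
    return pd.DataFrame(rows)
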