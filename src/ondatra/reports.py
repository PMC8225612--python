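"""Analysis surfaces and virtual sampling.

* dispersal flux: per-hexagon count of distinct dispersing individuals whose
  walk path crossed the cell in a year, and year-to-year difference maps;
* productivity: births − deaths per super-hexagon block, the source/sink
  measure, plus the percent of habitat area acting as source or sink;
* virtual trapping: per-site sampling of settled individuals and exhaustive
  first-order-relative tallies (mother–daughter or full siblings) from the
  true pedigree, split within vs between sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .hexgrid import HexGrid, SuperHexPartition
from .movement import WalkOutcome

FOUNDER = -1


@dataclass
class SiteDef:
    """A labelled sampling polygon and the hexagons it contains."""

    label: str
    polygon: object               # shapely polygon
    members: np.ndarray           # flat cell indices inside the polygon


# ---------------------------------------------------------------------------
# Dispersal flux


def flux_map(outcomes: list[WalkOutcome], grid: HexGrid,
             count_visits: bool = False) -> np.ndarray:
    """Per-hexagon disperser tally for one year of walks.

    By default an individual crossing a cell several times counts once
    (distinct-individual flux); ``count_visits=True`` tallies every step
    instead.
    """
    flux = np.zeros(grid.n_cells, dtype=np.int64)
    for o in outcomes:
        accumulate_flux(flux, o, count_visits=count_visits)
    return flux


def accumulate_flux(flux: np.ndarray, outcome: WalkOutcome,
                    count_visits: bool = False) -> None:
    if count_visits:
        np.add.at(flux, outcome.path, 1)
    else:
        flux[np.unique(outcome.path)] += 1


def flux_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signed per-hexagon difference of two (mean) flux maps, a − b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("flux maps are on different grids")
    return a - b


# ---------------------------------------------------------------------------
# Source-sink productivity


def productivity_map(births: np.ndarray, deaths: np.ndarray,
                     partition: SuperHexPartition) -> np.ndarray:
    """Per-block births − deaths from per-hexagon event tallies."""
    births = np.asarray(births)
    deaths = np.asarray(deaths)
    if births.shape != deaths.shape or births.shape != partition.block_of.shape:
        raise ValueError("ledger arrays must match the partitioned grid")
    net = births.astype(np.int64) - deaths.astype(np.int64)
    return np.bincount(partition.block_of, weights=net,
                       minlength=partition.n_blocks).astype(np.int64)


def source_sink_extent(block_values: np.ndarray,
                       partition: SuperHexPartition,
                       habitat_blocks: np.ndarray | None = None) -> float:
    """Percent of (habitat-bearing) block area with nonzero productivity.

    ``habitat_blocks`` is a boolean per-block mask restricting the denominator
    to blocks containing any settleable habitat; when omitted all blocks
    count.  Areas are actual block areas, so clipped edge blocks weigh less.
    """
    block_values = np.asarray(block_values)
    areas = partition.block_areas_km2()
    if habitat_blocks is None:
        habitat_blocks = np.ones(partition.n_blocks, dtype=bool)
    denom = areas[habitat_blocks].sum()
    if denom == 0:
        return 0.0
    num = areas[habitat_blocks & (block_values != 0)].sum()
    return 100.0 * num / denom


def habitat_block_mask(settleable: np.ndarray, partition: SuperHexPartition) -> np.ndarray:
    """Blocks containing at least one settleable hexagon."""
    counts = np.bincount(partition.block_of, weights=settleable.astype(float),
                         minlength=partition.n_blocks)
    return counts > 0


# ---------------------------------------------------------------------------
# Virtual trapping and pedigree relatedness


@dataclass
class RelatednessTally:
    year: int
    pairs_within: int
    pairs_between: int
    per_site_pair: dict[tuple[str, str], int]
    possible_within: int
    possible_between: int

    @property
    def total_pairs(self) -> int:
        return self.pairs_within + self.pairs_between

    @property
    def per_mil_within(self) -> float:
        return 1000.0 * self.pairs_within / self.possible_within if self.possible_within else 0.0

    @property
    def per_mil_between(self) -> float:
        return 1000.0 * self.pairs_between / self.possible_between if self.possible_between else 0.0

    @property
    def between_share(self) -> float:
        return self.pairs_between / self.total_pairs if self.total_pairs else float("nan")


def virtual_sample(homes: dict[int, int], sites: list[SiteDef], n_per_site: int,
                   rng: np.random.Generator) -> dict[str, list[int]]:
    """Sample up to ``n_per_site`` settled individuals per site, uniformly
    without replacement.

    ``homes`` maps individual id → flat home cell for the living, settled
    population in the sampling year.
    """
    ids = np.fromiter(homes.keys(), dtype=np.int64, count=len(homes))
    cells = np.fromiter(homes.values(), dtype=np.int64, count=len(homes))
    out: dict[str, list[int]] = {}
    for site in sites:
        member_set = np.isin(cells, site.members)
        present = ids[member_set]
        if present.size <= n_per_site:
            out[site.label] = sorted(int(i) for i in present)
        else:
            pick = rng.choice(present, size=n_per_site, replace=False)
            out[site.label] = sorted(int(i) for i in pick)
    return out


def is_first_order(a: int, b: int, mother_of: dict[int, int]) -> bool:
    """Parent–offspring or same-mother (full-sibling) pair in the pedigree."""
    ma = mother_of.get(a, FOUNDER)
    mb = mother_of.get(b, FOUNDER)
    if ma == b or mb == a:
        return True
    return ma != FOUNDER and ma == mb


def first_order_tally(sample: dict[str, list[int]], mother_of: dict[int, int],
                      year: int = 0) -> RelatednessTally:
    """Classify every sampled pair; split within-site vs between-site.

    Possible-pair denominators follow the sampling design: within = Σ C(n_s,2)
    per site, between = Σ n_s·n_t over site pairs.
    """
    labels = sorted(sample)
    within = 0
    between = 0
    per_pair: dict[tuple[str, str], int] = {}
    for s in labels:
        for a, b in combinations(sample[s], 2):
            if is_first_order(a, b, mother_of):
                within += 1
                per_pair[(s, s)] = per_pair.get((s, s), 0) + 1
    for i, s in enumerate(labels):
        for t in labels[i + 1:]:
            for a in sample[s]:
                for b in sample[t]:
                    if is_first_order(a, b, mother_of):
                        between += 1
                        per_pair[(s, t)] = per_pair.get((s, t), 0) + 1
    ns = {s: len(sample[s]) for s in labels}
    poss_within = sum(n * (n - 1) // 2 for n in ns.values())
    poss_between = sum(
        ns[s] * ns[t] for i, s in enumerate(labels) for t in labels[i + 1:]
    )
    return RelatednessTally(year, within, between, per_pair, poss_within, poss_between)
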