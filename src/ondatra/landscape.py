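"""Annual habitat and dispersal surfaces from land/shoreline/water maps.

A year's landscape enters as a binary land/water raster.  The shoreline — the
one-pixel band on either side of the land/water interface — is extracted by a
neighbourhood scan, yielding a three-class map.  From it two per-hexagon
surfaces are built:

* the *dispersal surface*: water and shoreline score 10, land scores 0,
  area-averaged into each hexagon, so a cell's movement resistance is
  ``10 − score`` (land 10, open water 0, shoreline fringe in between);
* the *habitat surface*: the shoreline-pixel area fraction of each hexagon,
  in [0, 1].  Muskrat home ranges sit on the vegetated fringe, so open water
  is traversable but not settleable; a hexagon is settleable when its
  suitability reaches ``settle_threshold``.

In flood years movement uses a constant score-10 surface (no resistance
anywhere).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .hexgrid import HexGrid, resample_raster

LAND = 0
SHORELINE = 1
WATER = 2

_4CONN = ndimage.generate_binary_structure(2, 1)


@dataclass
class LandCoverRaster:
    """Three-class (land / shoreline / water) pixel map for one year."""

    classes: np.ndarray          # 2-D int array of LAND/SHORELINE/WATER
    resolution: float            # pixel size, metres
    year: int
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        bad = ~np.isin(self.classes, (LAND, SHORELINE, WATER))
        if bad.any():
            raise ValueError("land-cover raster contains classes outside {LAND, SHORELINE, WATER}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape


def extract_shoreline(
    water: np.ndarray,
    resolution: float,
    year: int = 0,
    origin: tuple[float, float] = (0.0, 0.0),
    buffer_px: int = 1,
) -> LandCoverRaster:
    """Classify a binary land/water raster into land / shoreline / water.

    Pixels within ``buffer_px`` (4-neighbourhood) of the land/water interface,
    on either side of it, become SHORELINE.  On binary input this interface
    band is exactly the limit of an edge-detection pass, so no gradient
    filtering is needed.  Idempotent in the sense that re-extracting from the
    implied water mask (water ∪ water-side shoreline) reproduces the result.
    """
    if isinstance(water, LandCoverRaster):
        return water  # already classified: re-running changes nothing
    water = np.asarray(water)
    vals = np.unique(water)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("input raster must be binary (0 = land, 1 = water)")
    water = water.astype(bool)
    land = ~water
    near_water = ndimage.binary_dilation(water, _4CONN, iterations=buffer_px)
    near_land = ndimage.binary_dilation(land, _4CONN, iterations=buffer_px)
    shoreline = (land & near_water) | (water & near_land)
    classes = np.where(water, WATER, LAND)
    classes[shoreline] = SHORELINE
    return LandCoverRaster(classes, resolution, year, origin)


def make_dispersal_surface(grid: HexGrid, lc: LandCoverRaster, subsample: int = 4) -> np.ndarray:
    """Per-hexagon movement score in [0, 10] (resistance = 10 − score)."""
    scores = np.where(lc.classes == LAND, 0.0, 10.0)
    return resample_raster(grid, scores, lc.resolution, lc.origin, subsample=subsample)


def make_habitat_surface(grid: HexGrid, lc: LandCoverRaster, subsample: int = 4) -> np.ndarray:
    """Per-hexagon suitability in [0, 1]: the shoreline area fraction."""
    frac = (lc.classes == SHORELINE).astype(float)
    return resample_raster(grid, frac, lc.resolution, lc.origin, subsample=subsample)


def make_flood_surface(grid: HexGrid) -> np.ndarray:
    """Constant score-10 surface: zero resistance everywhere during floods."""
    return np.full(grid.n_cells, 10.0)


@dataclass
class AtlasYear:
    land_cover: LandCoverRaster
    dispersal: np.ndarray        # per-hex score, [0, 10]
    habitat: np.ndarray          # per-hex suitability, [0, 1]
    flood: bool


@dataclass
class AnnualAtlas:
    """Stack of per-year landscapes sharing one hexagonal grid."""

    grid: HexGrid
    years: dict[int, AtlasYear] = field(default_factory=dict)
    settle_threshold: float = 0.1

    def add_year(self, year: int, water: np.ndarray, resolution: float, flood: bool,
                 origin: tuple[float, float] = (0.0, 0.0), subsample: int = 4) -> AtlasYear:
        lc = extract_shoreline(water, resolution, year, origin)
        ay = AtlasYear(
            land_cover=lc,
            dispersal=make_dispersal_surface(self.grid, lc, subsample),
            habitat=make_habitat_surface(self.grid, lc, subsample),
            flood=flood,
        )
        self.years[year] = ay
        return ay

    def year_list(self) -> list[int]:
        return sorted(self.years)

    def settleable(self, year: int) -> np.ndarray:
        """Boolean per-hex mask of cells that can host a home range."""
        return self.years[year].habitat >= self.settle_threshold

    def water_area_series(self) -> dict[int, int]:
        return {
            y: int((ay.land_cover.classes != LAND).sum()) for y, ay in self.years.items()
        }

    def habitat_area_series(self) -> dict[int, int]:
        return {y: int(self.settleable(y).sum()) for y in self.years}
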