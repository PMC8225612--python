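"""Synthetic multi-year floodplain atlases.

Generates the kind of landscape the simulator consumes without any satellite
input: a land matrix holding a mosaic of lakes (discs) strung along river
corridors (buffered polylines), plus optional isolated ponds off the corridor
network.  Year over year the water mask is updated on a flood/dry schedule —
flood years dilate every water body until its area has grown by the configured
expansion factor; other years erode boundary pixels at the drying rate.  A
thin "perennial core" (river centrelines and connected-lake centres) is never
eroded, standing in for permanent channels; isolated ponds have no such core
and can disappear entirely under sustained drying.

Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely import contains_xy
from shapely.geometry import Point
from sklearn.cluster import KMeans

from .hexgrid import HexGrid
from .landscape import AnnualAtlas
from .reports import SiteDef

_4CONN = ndimage.generate_binary_structure(2, 1)


class CannotPlaceSites(RuntimeError):
    """Raised when the atlas lacks enough persistent habitat for the sites."""


@dataclass
class DeltaScenario:
    """Parameters of one synthetic delta."""

    n_rows: int = 200
    n_per_row: int = 200
    cell_width: float = 60.0
    resolution: float = 60.0          # raster pixel size, metres
    n_years: int = 47
    start_year: int = 0
    flood_years: tuple[int, ...] = (5, 20)
    flood_expansion: float = 2.0      # water-area multiplier in a flood year
    drying_rate: float = 0.03        # water-area fraction lost per non-flood year
    n_lakes: int = 6                  # lakes strung on the river corridor
    lake_radius_px: tuple[int, int] = (6, 10)
    n_isolated: int = 2               # ponds with no corridor connection
    isolated_radius_px: tuple[int, int] = (4, 6)
    river_width_px: int = 3
    marsh_island_fraction: float = 0.35  # raised-ground fraction inside flooded zones
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flood_expansion < 1.0:
            raise ValueError("flood expansion factor must be >= 1")
        if not 0.0 <= self.drying_rate < 1.0:
            raise ValueError("drying rate must be in [0, 1)")
        max_r = max(self.lake_radius_px[1], self.isolated_radius_px[1])
        if 2 * max_r >= min(self.raster_shape):
            raise ValueError("lakes larger than the raster")

    @property
    def grid(self) -> HexGrid:
        return HexGrid(self.n_rows, self.n_per_row, self.cell_width)

    @property
    def raster_shape(self) -> tuple[int, int]:
        g = self.grid
        h = math.ceil((g.n_rows * g.row_spacing + g.cell_width) / self.resolution)
        w = math.ceil((g.n_per_row + 0.5) * g.cell_width / self.resolution)
        return (h, w)

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))


def _disc(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _polyline_band(shape: tuple[int, int], points: np.ndarray, half_width: float) -> np.ndarray:
    """Pixels within half_width of a polyline (pixel units)."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dist = np.full(shape, np.inf)
    for (y0, x0), (y1, x1) in zip(points[:-1], points[1:]):
        dy, dx = y1 - y0, x1 - x0
        L2 = dy * dy + dx * dx
        if L2 == 0:
            d = np.hypot(yy - y0, xx - x0)
        else:
            t = np.clip(((yy - y0) * dy + (xx - x0) * dx) / L2, 0.0, 1.0)
            d = np.hypot(yy - (y0 + t * dy), xx - (x0 + t * dx))
        dist = np.minimum(dist, d)
    return dist <= half_width


def _grow(water: np.ndarray, target: int, depth: np.ndarray,
          island: np.ndarray) -> np.ndarray:
    """Flood outward until the water area reaches target, deepest land first.

    ``island`` pixels (slightly raised ground) are skipped, so newly flooded
    zones come up as a water/land mosaic — the marsh fringe that constitutes
    muskrat habitat — rather than as solid open water.
    """
    water = water.copy()
    area = int(water.sum())
    flat_depth = depth.ravel()
    while area < target:
        cand = np.flatnonzero(
            ndimage.binary_dilation(water, _4CONN) & ~water & ~island
        )
        if cand.size == 0:
            break  # no floodable ground left: the flood caps below target
        k = min(target - area, cand.size)
        take = cand[np.argsort(flat_depth[cand])[::-1][:k]]
        water.ravel()[take] = True
        area += k
    return water


def _shrink(water: np.ndarray, target: int, keep: np.ndarray,
            depth: np.ndarray) -> np.ndarray:
    """Dry the waterline down to target area, shallowest exposed water first.

    Marsh-mosaic water borders land everywhere, so entire shallow zones are
    eligible at once and empty before the deep solid lakes and channels are
    touched; habitat therefore contracts as drying proceeds.
    """
    water = water.copy()
    area = int(water.sum())
    flat_depth = depth.ravel()
    while area > target:
        boundary = water & ndimage.binary_dilation(~water, _4CONN) & ~keep
        cand = np.flatnonzero(boundary)
        if cand.size == 0:
            break
        k = min(area - target, cand.size)
        take = cand[np.argsort(flat_depth[cand])[:k]]
        water.ravel()[take] = False
        area -= k
    return water


@dataclass
class DeltaGeometry:
    """Pixel-space layout of the generated water bodies."""

    river_points: np.ndarray          # polyline knots, (y, x) pixel coords
    lake_centers: list[tuple[float, float]]
    lake_radii: list[int]
    pond_centers: list[tuple[float, float]]
    pond_radii: list[int]

    def region_cells(self, scenario: DeltaScenario, which: str, index: int,
                     pad_px: float = 6.0) -> np.ndarray:
        """Flat hex indices around one lake (``which="lake"``) or pond."""
        cy, cx = (self.lake_centers if which == "lake" else self.pond_centers)[index]
        r = (self.lake_radii if which == "lake" else self.pond_radii)[index]
        res = scenario.resolution
        cxw, cyw = (cx + 0.5) * res, (cy + 0.5) * res
        centers = scenario.grid.centers()
        d2 = (centers[:, 0] - cxw) ** 2 + (centers[:, 1] - cyw) ** 2
        return np.flatnonzero(d2 <= ((r + pad_px) * res) ** 2)


def generate_layout(scenario: DeltaScenario,
                    rng: np.random.Generator | None = None
                    ) -> tuple[np.ndarray, np.ndarray, DeltaGeometry]:
    """Initial water mask, perennial core and geometry for a scenario.

    Deterministic given the scenario seed; ``generate_water_masks`` consumes
    the same draws first, so the layout can be recomputed independently.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    shape = scenario.raster_shape
    h, w = shape

    # main river: left-to-right polyline with vertical wiggle
    n_knots = 5
    xs = np.linspace(0, w - 1, n_knots)
    ys = h / 2 + rng.uniform(-h / 8, h / 8, size=n_knots)
    river_pts = np.column_stack([ys, xs])
    river = _polyline_band(shape, river_pts, scenario.river_width_px / 2 + 0.5)
    core = _polyline_band(shape, river_pts, 0.5)

    water = river.copy()
    lake_centers, lake_radii = [], []
    # connected lakes: centres on the river polyline, evenly spread
    fracs = np.linspace(0.12, 0.88, scenario.n_lakes)
    for f in fracs:
        t = f * (n_knots - 1)
        i = min(int(t), n_knots - 2)
        a = t - i
        cy = (1 - a) * river_pts[i, 0] + a * river_pts[i + 1, 0]
        cx = (1 - a) * river_pts[i, 1] + a * river_pts[i + 1, 1]
        r = int(rng.integers(scenario.lake_radius_px[0], scenario.lake_radius_px[1] + 1))
        water |= _disc(shape, (cy, cx), r)
        core |= _disc(shape, (cy, cx), 1.5)
        lake_centers.append((cy, cx))
        lake_radii.append(r)

    # isolated ponds: well away from the river, no perennial core; on cramped
    # rasters the required gap is relaxed progressively
    pond_centers, pond_radii = [], []
    base_gap = scenario.isolated_radius_px[1] + scenario.lake_radius_px[1] + 8
    for gap_scale in (1.0, 0.7, 0.5, 0.35):
        gap = max(3, int(round(base_gap * gap_scale)))
        for _ in range(200):
            if len(pond_centers) >= scenario.n_isolated:
                break
            cy = rng.uniform(0.1 * h, 0.9 * h)
            cx = rng.uniform(0.1 * w, 0.9 * w)
            r = int(rng.integers(scenario.isolated_radius_px[0],
                                 scenario.isolated_radius_px[1] + 1))
            probe = _disc(shape, (cy, cx), r + gap)
            if not (probe & water).any():
                water |= _disc(shape, (cy, cx), r)
                pond_centers.append((cy, cx))
                pond_radii.append(r)
        if len(pond_centers) >= scenario.n_isolated:
            break

    geometry = DeltaGeometry(river_pts, lake_centers, lake_radii,
                             pond_centers, pond_radii)
    return water, core, geometry


def generate_water_masks(scenario: DeltaScenario) -> dict[int, np.ndarray]:
    """Per-year binary water masks following the flood/dry schedule."""
    rng = np.random.default_rng(scenario.seed)
    shape = scenario.raster_shape
    water, core, geometry = generate_layout(scenario, rng)

    # synthetic bathymetry: smooth noise, deeper toward existing water
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=4.0)
    noise /= max(noise.std(), 1e-12)
    dist_to_water = ndimage.distance_transform_edt(~water)
    depth = noise - 0.15 * dist_to_water + 0.02 * rng.standard_normal(shape)
    # isolated ponds sit in shallow perched basins: first to dry, last to flood
    for (cy, cx), r in zip(geometry.pond_centers, geometry.pond_radii):
        depth[_disc(shape, (cy, cx), r + 6)] -= 1.2
    # raised ground left dry inside flooded zones (the marsh mosaic)
    fine = rng.standard_normal(shape)
    island = (fine > np.quantile(fine, 1.0 - scenario.marsh_island_fraction)) & ~water

    masks: dict[int, np.ndarray] = {}
    for i, year in enumerate(scenario.years):
        if i == 0:
            masks[year] = water.copy()
            continue
        prev = masks[year - 1]
        area = int(prev.sum())
        if year in scenario.flood_years:
            target = max(area + 1, int(round(area * scenario.flood_expansion)))
            masks[year] = _grow(prev, target, depth, island)
        else:
            target = int(math.floor(area * (1.0 - scenario.drying_rate)))
            masks[year] = _shrink(prev, target, core, depth)
    return masks


def generate_atlas(scenario: DeltaScenario, settle_threshold: float = 0.1,
                   subsample: int = 4) -> AnnualAtlas:
    """Build the full annual atlas (rasters + per-hex surfaces) for a scenario."""
    masks = generate_water_masks(scenario)
    atlas = AnnualAtlas(scenario.grid, settle_threshold=settle_threshold)
    for year in scenario.years:
        atlas.add_year(
            year,
            masks[year].astype(np.uint8),
            scenario.resolution,
            flood=year in scenario.flood_years,
            subsample=subsample,
        )
    return atlas


def place_sites(atlas: AnnualAtlas, n_sites: int, seed: int = 0) -> list[SiteDef]:
    """Disjoint labelled sampling polygons over persistent habitat.

    The shoreline fringe migrates as water bodies swell and shrink, so no
    single hexagon need stay settleable across all years; instead, hexagons
    settleable in at least half the atlas years are clustered spatially
    (k-means) and each site polygon — the buffered convex hull of a cluster —
    is grown until it contains at least one settleable hexagon in *every*
    year.  Labels run A, B, … ordered west to east.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    years = atlas.year_list()
    freq = np.zeros(atlas.grid.n_cells)
    for y in years:
        freq += atlas.settleable(y)
    freq /= len(years)
    cells = np.flatnonzero(freq >= 0.5)
    if cells.size < n_sites:
        cells = np.flatnonzero(freq > 0)
    if cells.size < n_sites:
        raise CannotPlaceSites(
            f"only {cells.size} habitat-bearing hexagons for {n_sites} sites"
        )
    centers = atlas.grid.centers()[cells]
    km = KMeans(n_clusters=n_sites, random_state=seed, n_init=4).fit(centers)
    centroids = km.cluster_centers_
    order = np.argsort(centroids[:, 0])

    all_centers = atlas.grid.centers()
    w = atlas.grid.cell_width
    settle_by_year = {y: atlas.settleable(y) for y in years}

    # disc polygons, disjoint by construction: each radius stays below half
    # the distance to the nearest other centroid
    if n_sites == 1:
        extent = np.hypot(atlas.grid.n_per_row * w,
                          atlas.grid.n_rows * atlas.grid.row_spacing)
        gaps = np.array([extent])
    else:
        gaps = np.array(
            [
                min(
                    np.hypot(*(centroids[k] - centroids[j]))
                    for j in range(n_sites)
                    if j != k
                )
                for k in range(n_sites)
            ]
        )
    sites = []
    for label_i, k in enumerate(order):
        # the largest disc that cannot touch a neighbouring site, capped at a
        # 1.5 km trapping radius so a site stays a local water body
        radius = min(0.45 * gaps[k], 25.0 * w)
        poly = Point(centroids[k]).buffer(radius, quad_segs=16)
        members = np.flatnonzero(
            contains_xy(poly, all_centers[:, 0], all_centers[:, 1])
        )
        if not members.size or not all(
            settle_by_year[y][members].any() for y in years
        ):
            raise CannotPlaceSites(
                f"cluster {label_i} lacks settleable habitat in some year"
            )
        sites.append(SiteDef(label=chr(ord("A") + label_i), polygon=poly, members=members))
    return sites
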