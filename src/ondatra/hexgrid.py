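"""Hexagonal lattice geometry.

The simulation landscape is a lattice of pointy-top regular hexagons laid out
in offset rows ("odd-r" convention: odd rows are shifted half a cell to the
right).  ``cell_width`` is the flat-to-flat diameter in metres, which equals
the centre spacing of adjacent cells within a row; the area of one cell is
(√3/2)·width².  World coordinates are planar metres with y increasing with the
row index, matching raster row order.

Cells are addressed either by :class:`HexCoord` (row, col) or by a flat index
``row * n_per_row + col``; the flat form is used throughout the movement and
demography code for speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

SQRT3 = math.sqrt(3.0)

# Neighbour slots in fixed angular order and their planar unit vectors
# (y grows downward, so "NE" decreases the row index).
DIRECTIONS = ("E", "NE", "NW", "W", "SW", "SE")
DIRECTION_VECTORS = np.array(
    [
        (1.0, 0.0),
        (0.5, -SQRT3 / 2),
        (-0.5, -SQRT3 / 2),
        (-1.0, 0.0),
        (-0.5, SQRT3 / 2),
        (0.5, SQRT3 / 2),
    ]
)

# (drow, dcol) per slot, for even and odd rows (odd-r offset layout).
_OFFSETS_EVEN = ((0, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0))
_OFFSETS_ODD = ((0, 1), (-1, 1), (-1, 0), (0, -1), (1, 0), (1, 1))


class HexCoord(NamedTuple):
    row: int
    col: int


@dataclass(frozen=True)
class HexGrid:
    """An ``n_rows`` × ``n_per_row`` offset-row hexagonal lattice."""

    n_rows: int
    n_per_row: int
    cell_width: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_per_row < 1:
            raise ValueError("grid dimensions must be positive")
        if self.cell_width <= 0:
            raise ValueError("cell width must be positive")

    # -- scalar geometry -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_per_row

    @property
    def cell_area_m2(self) -> float:
        return (SQRT3 / 2.0) * self.cell_width**2

    @property
    def cell_area_ha(self) -> float:
        return self.cell_area_m2 / 1.0e4

    @property
    def row_spacing(self) -> float:
        """Vertical distance between row centres: (√3/2)·width."""
        return (SQRT3 / 2.0) * self.cell_width

    # -- indexing --------------------------------------------------------

    def index(self, c: HexCoord | tuple[int, int]) -> int:
        row, col = c
        if not (0 <= row < self.n_rows and 0 <= col < self.n_per_row):
            raise ValueError(f"coordinate {c!r} outside {self.n_rows}x{self.n_per_row} grid")
        return row * self.n_per_row + col

    def coord(self, idx: int) -> HexCoord:
        row, col = divmod(int(idx), self.n_per_row)
        if not 0 <= row < self.n_rows:
            raise ValueError(f"flat index {idx} out of range")
        return HexCoord(row, col)

    def contains(self, c: tuple[int, int]) -> bool:
        row, col = c
        return 0 <= row < self.n_rows and 0 <= col < self.n_per_row

    # -- world coordinates ----------------------------------------------

    def center(self, c: HexCoord | tuple[int, int]) -> tuple[float, float]:
        row, col = c
        x0, y0 = self.origin
        x = x0 + (col + 0.5 * (row & 1)) * self.cell_width
        y = y0 + row * self.row_spacing
        return (x, y)

    def centers(self) -> np.ndarray:
        """(n_cells, 2) array of cell centre coordinates in flat-index order."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_per_row)
        x0, y0 = self.origin
        x = x0 + (cols + 0.5 * (rows & 1)) * self.cell_width
        y = y0 + rows * self.row_spacing
        return np.column_stack([x, y])

    def point_to_cell(self, x: float, y: float) -> HexCoord | None:
        """The cell whose hexagon contains the point, or None when outside."""
        row, col = self._points_to_rc(np.asarray([x]), np.asarray([y]))
        r, c = int(row[0]), int(col[0])
        return HexCoord(r, c) if self.contains((r, c)) else None

    def _points_to_rc(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised point → (row, col); results may be out of bounds."""
        x0, y0 = self.origin
        w = self.cell_width
        rf = (y - y0) / self.row_spacing            # fractional axial r
        qf = (x - x0) / w - rf / 2.0                # fractional axial q
        q, r = _cube_round(qf, rf)
        col = q + (r - (r & 1)) // 2
        return r, col

    # -- axial conversions ----------------------------------------------

    def to_axial(self, c: HexCoord | tuple[int, int]) -> tuple[int, int]:
        row, col = c
        return (col - (row - (row & 1)) // 2, row)

    def from_axial(self, q: int, r: int) -> HexCoord:
        return HexCoord(r, q + (r - (r & 1)) // 2)

    # -- adjacency and distance ------------------------------------------

    def neighbors(self, c: HexCoord | tuple[int, int]) -> list[HexCoord]:
        row, col = c
        if not self.contains((row, col)):
            raise ValueError(f"coordinate {c!r} outside grid")
        offs = _OFFSETS_ODD if row & 1 else _OFFSETS_EVEN
        out = []
        for dr, dc in offs:
            rr, cc = row + dr, col + dc
            if 0 <= rr < self.n_rows and 0 <= cc < self.n_per_row:
                out.append(HexCoord(rr, cc))
        return out

    def neighbors_array(self) -> np.ndarray:
        """(n_cells, 6) flat neighbour indices per slot, -1 where off-grid.

        Slot order follows :data:`DIRECTIONS`. Cached on first call.
        """
        cached = getattr(self, "_nbr_cache", None)
        if cached is not None:
            return cached
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_per_row)
        out = np.full((self.n_cells, 6), -1, dtype=np.int64)
        for k in range(6):
            dr_e, dc_e = _OFFSETS_EVEN[k]
            dr_o, dc_o = _OFFSETS_ODD[k]
            odd = (rows & 1).astype(bool)
            rr = np.where(odd, rows + dr_o, rows + dr_e)
            cc = np.where(odd, cols + dc_o, cols + dc_e)
            ok = (rr >= 0) & (rr < self.n_rows) & (cc >= 0) & (cc < self.n_per_row)
            out[ok, k] = rr[ok] * self.n_per_row + cc[ok]
        object.__setattr__(self, "_nbr_cache", out)
        return out

    def hex_distance(self, a: HexCoord | tuple[int, int], b: HexCoord | tuple[int, int]) -> int:
        """Minimal number of steps between two cells (unbounded lattice)."""
        qa, ra = self.to_axial(a)
        qb, rb = self.to_axial(b)
        dq, dr = qa - qb, ra - rb
        return (abs(dq) + abs(dr) + abs(dq + dr)) // 2


# ---------------------------------------------------------------------------
# Super-hexagon tessellation


def superhex_block_size(radius: int) -> int:
    """Cells in a full (interior) super-hexagon of the given radius."""
    return 1 + 3 * radius * (radius + 1)


@dataclass
class SuperHexPartition:
    """Partition of a grid into hexagonal blocks of unit-cell radius ``radius``.

    Interior blocks contain ``1 + 3·r·(r+1)`` cells; blocks clipped by the grid
    boundary keep their actual cell count.
    """

    grid: HexGrid
    radius: int
    block_of: np.ndarray          # flat cell index -> block id
    n_blocks: int
    block_sizes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.block_sizes = np.bincount(self.block_of, minlength=self.n_blocks)

    @property
    def interior_block_area_m2(self) -> float:
        return superhex_block_size(self.radius) * self.grid.cell_area_m2

    @property
    def interior_block_area_km2(self) -> float:
        return self.interior_block_area_m2 / 1.0e6

    def block_areas_km2(self) -> np.ndarray:
        return self.block_sizes * self.grid.cell_area_m2 / 1.0e6


def superhex_partition(grid: HexGrid, radius: int) -> SuperHexPartition:
    """Tessellate the grid into super-hexagons of the given radius.

    Block centres form a sub-lattice with axial basis (2r+1, −r), (r, r+1);
    every cell is assigned to the unique centre within hex distance r.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    n = grid.n_cells
    if radius == 0:
        return SuperHexPartition(grid, 0, np.arange(n, dtype=np.int64), n)

    rows, cols = np.divmod(np.arange(n), grid.n_per_row)
    q = cols - (rows - (rows & 1)) // 2
    r = rows
    m = superhex_block_size(radius)
    # lattice coordinates (a, b) with centre = a·(2r+1, −r) + b·(r, r+1)
    af = ((radius + 1) * q - radius * r) / m
    bf = (radius * q + (2 * radius + 1) * r) / m
    a0 = np.rint(af).astype(np.int64)
    b0 = np.rint(bf).astype(np.int64)

    best_a = np.zeros(n, dtype=np.int64)
    best_b = np.zeros(n, dtype=np.int64)
    best_d = np.full(n, np.iinfo(np.int64).max)
    for da in (-1, 0, 1):
        for db in (-1, 0, 1):
            a = a0 + da
            b = b0 + db
            cq = a * (2 * radius + 1) + b * radius
            cr = -a * radius + b * (radius + 1)
            dq = q - cq
            dr = r - cr
            d = (np.abs(dq) + np.abs(dr) + np.abs(dq + dr)) // 2
            take = d < best_d
            best_d[take] = d[take]
            best_a[take] = a[take]
            best_b[take] = b[take]

    key = best_a * (2 * n + 1) + best_b
    _, block_of = np.unique(key, return_inverse=True)
    return SuperHexPartition(grid, radius, block_of.astype(np.int64), int(block_of.max()) + 1)


# ---------------------------------------------------------------------------
# Raster → hexagon resampling


def resample_raster(
    grid: HexGrid,
    raster: np.ndarray,
    pixel_size: float,
    raster_origin: tuple[float, float] = (0.0, 0.0),
    subsample: int = 4,
    fill: float = 0.0,
) -> np.ndarray:
    """Area-weighted mean of pixel values per hexagon.

    Each pixel is split into ``subsample²`` equal sub-areas represented by
    their centre points; a hexagon's value is the mean over sub-points that
    fall inside it, which converges to the polygon-clipped area-weighted mean.
    Hexagons receiving no sub-point take ``fill``.

    ``raster_origin`` is the world coordinate of the raster's upper-left
    corner (pixel row 0 is the smallest y, matching grid row order).
    """
    raster = np.asarray(raster, dtype=float)
    if raster.ndim != 2:
        raise ValueError("raster must be 2-D")
    if subsample < 1:
        raise ValueError("subsample must be >= 1")
    h, w = raster.shape
    x0, y0 = raster_origin
    s = subsample
    # sub-point world coordinates
    xs = x0 + (np.arange(w * s) + 0.5) * (pixel_size / s)
    ys = y0 + (np.arange(h * s) + 0.5) * (pixel_size / s)
    xx, yy = np.meshgrid(xs, ys)
    rr, cc = grid._points_to_rc(xx.ravel(), yy.ravel())
    ok = (rr >= 0) & (rr < grid.n_rows) & (cc >= 0) & (cc < grid.n_per_row)
    if not ok.any():
        raise ValueError("raster extent does not overlap the grid")
    flat = rr[ok] * grid.n_per_row + cc[ok]
    vals = np.repeat(np.repeat(raster, s, axis=0), s, axis=1).ravel()[ok]
    sums = np.bincount(flat, weights=vals, minlength=grid.n_cells)
    counts = np.bincount(flat, minlength=grid.n_cells)
    out = np.full(grid.n_cells, float(fill))
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


# ---------------------------------------------------------------------------


def _cube_round(qf: np.ndarray, rf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Round fractional axial coordinates to the nearest hexagon."""
    xf = qf
    zf = rf
    yf = -xf - zf
    x = np.rint(xf)
    y = np.rint(yf)
    z = np.rint(zf)
    dx = np.abs(x - xf)
    dy = np.abs(y - yf)
    dz = np.abs(z - zf)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    x = np.where(fix_x, -y - z, x)
    z = np.where(fix_z, -x - y, z)
    return x.astype(np.int64), z.astype(np.int64)


def disk_offsets(radius: int) -> list[list[tuple[int, int]]]:
    """Axial offsets grouped by hex distance 0..radius, ring by ring.

    Used by the exploration scan (nearest-first search of the local
    neighbourhood).
    """
    rings: list[list[tuple[int, int]]] = [[] for _ in range(radius + 1)]
    for dq in range(-radius, radius + 1):
        for dr in range(-radius, radius + 1):
            d = (abs(dq) + abs(dr) + abs(dq + dr)) // 2
            if d <= radius:
                rings[d].append((dq, dr))
    return rings
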