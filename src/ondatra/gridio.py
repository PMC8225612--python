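"""Plain-text raster and surface I/O.

Rasters travel as ESRI ASCII grids (``.asc``): a six-line header followed by
whitespace-separated rows, row 0 at the top (largest y in the usual
north-up convention; this package's world frame has y growing with the row
index, so rows are stored in index order and ``yllcorner`` records the frame
origin).  Per-hexagon surfaces are saved as a dense text array plus a JSON
sidecar recording grid dimensions, cell width and origin.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .hexgrid import HexGrid


def write_ascii_grid(path, data: np.ndarray, cellsize: float,
                     xllcorner: float = 0.0, yllcorner: float = 0.0,
                     nodata: float = -9999) -> None:
    data = np.asarray(data)
    header = (
        f"ncols {data.shape[1]}\n"
        f"nrows {data.shape[0]}\n"
        f"xllcorner {xllcorner}\n"
        f"yllcorner {yllcorner}\n"
        f"cellsize {cellsize}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%g")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    meta = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    expect = (int(meta["nrows"]), int(meta["ncols"]))
    if data.shape != expect:
        raise ValueError(f"grid body {data.shape} does not match header {expect}")
    return data, meta


def write_surface(path, grid: HexGrid, surface: np.ndarray) -> None:
    """Dense per-hexagon surface + JSON sidecar with the grid definition."""
    path = Path(path)
    np.savetxt(path, np.asarray(surface).reshape(grid.n_rows, grid.n_per_row), fmt="%g")
    sidecar = {
        "n_rows": grid.n_rows,
        "n_per_row": grid.n_per_row,
        "cell_width": grid.cell_width,
        "origin": list(grid.origin),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_surface(path) -> tuple[HexGrid, np.ndarray]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid = HexGrid(meta["n_rows"], meta["n_per_row"], meta["cell_width"],
                   tuple(meta["origin"]))
    surface = np.loadtxt(path).reshape(grid.n_cells)
    return grid, surface
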