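"""Gridded landscape layers (habitat, elevation, NDVI, slope, aspect).

All layers of a :class:`LandscapeGrid` share one regular grid in a projected
metric coordinate system.  Rasters are exchanged as plain-text ESRI ASCII
grids, one file per layer; categorical layers (habitat, aspect) are stored as
integer codes with the code tables fixed below.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "HABITAT_CLASSES",
    "ASPECT_CLASSES",
    "LandscapeGrid",
    "read_grid",
    "write_grid",
    "read_landscape",
    "write_landscape",
]

# habitat codes follow tree-height classes used by forestry inventories:
# bog (wet, unforested), clearcut (<1.3 m), young (1.3-10 m), mature (>10 m)
HABITAT_CLASSES = ("bog", "clearcut", "mature_forest", "young_forest", "other")
ASPECT_CLASSES = ("N", "E", "S", "W")

LAYER_NAMES = ("habitat", "elevation", "ndvi", "slope", "aspect")


@dataclass
class LandscapeGrid:
    """Co-registered landscape layers on one regular grid.

    ``x0, y0`` is the lower-left corner; arrays are stored row 0 = northernmost
    row (the ESRI ASCII convention).  ``habitat`` and ``aspect`` hold integer
    codes into :data:`HABITAT_CLASSES` / :data:`ASPECT_CLASSES`.
    """

    x0: float
    y0: float
    cell_size: float
    layers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {k: v.shape for k, v in self.layers.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"layers must share one grid, got shapes {shapes}")
        hab = self.layers.get("habitat")
        if hab is not None and not np.isin(hab, np.arange(len(HABITAT_CLASSES))).all():
            raise ValueError("habitat codes outside the 5-class set")

    @property
    def n_rows(self) -> int:
        return next(iter(self.layers.values())).shape[0]

    @property
    def n_cols(self) -> int:
        return next(iter(self.layers.values())).shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the gridded area."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.n_cols * self.cell_size,
            self.y0 + self.n_rows * self.cell_size,
        )

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= x <= xmax and ymin <= y <= ymax

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """Nearest-cell (row, col) for a point inside the extent.

        Points on a shared cell edge are equidistant from two cell centres;
        the tie breaks to the lower (row-major) index.
        """
        if not self.contains(x, y):
            raise ValueError(f"point ({x}, {y}) outside grid extent {self.extent}")
        col = int(np.ceil((x - self.x0) / self.cell_size)) - 1
        y_top = self.y0 + self.n_rows * self.cell_size
        row = int(np.ceil((y_top - y) / self.cell_size)) - 1
        return (min(max(row, 0), self.n_rows - 1), min(max(col, 0), self.n_cols - 1))

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        y_top = self.y0 + self.n_rows * self.cell_size
        return (
            self.x0 + (col + 0.5) * self.cell_size,
            y_top - (row + 0.5) * self.cell_size,
        )

    def value_at(self, layer: str, x: float, y: float):
        row, col = self.cell_index(x, y)
        return self.layers[layer][row, col]


def write_grid(path: str | os.PathLike, grid_values: np.ndarray, x0: float, y0: float,
               cell_size: float, nodata: float = -9999) -> None:
    """Write one layer as an ESRI ASCII grid (NaN -> NODATA_value)."""
    arr = np.asarray(grid_values, dtype=float)
    nrows, ncols = arr.shape
    out = arr.copy()
    out[~np.isfinite(out)] = nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {x0:.6f}\n")
        fh.write(f"yllcorner {y0:.6f}\n")
        fh.write(f"cellsize {cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_grid(path: str | os.PathLike) -> tuple[np.ndarray, float, float, float]:
    """Read one ESRI ASCII grid; returns (values, x0, y0, cell_size).

    NODATA cells come back as NaN.  Raises on malformed or incomplete headers.
    """
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(parts) == 2 and key in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    missing = required - set(header)
    if missing:
        raise ValueError(f"{path}: missing ESRI ASCII header fields {sorted(missing)}")
    arr = np.asarray(rows, dtype=float)
    if arr.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: data shape {arr.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value")
    if nodata is not None:
        arr[arr == nodata] = np.nan
    return arr, header["xllcorner"], header["yllcorner"], header["cellsize"]


def write_landscape(grid: LandscapeGrid, directory: str | os.PathLike) -> None:
    """Write every layer of a landscape as ``<directory>/<layer>.asc``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, values in grid.layers.items():
        write_grid(directory / f"{name}.asc", values.astype(float), grid.x0, grid.y0, grid.cell_size)


def read_landscape(directory: str | os.PathLike) -> LandscapeGrid:
    """Read a landscape written by :func:`write_landscape`.

    All ``.asc`` files in the directory are loaded; their headers must agree
    exactly (same grid), otherwise an error is raised.
    """
    directory = Path(directory)
    paths = sorted(directory.glob("*.asc"))
    if not paths:
        raise FileNotFoundError(f"no .asc layers found in {directory}")
    layers: dict[str, np.ndarray] = {}
    ref: tuple[float, float, float] | None = None
    for p in paths:
        arr, x0, y0, cs = read_grid(p)
        if ref is None:
            ref = (x0, y0, cs)
        elif (x0, y0, cs) != ref:
            raise ValueError(f"{p}: header ({x0}, {y0}, {cs}) differs from other layers {ref}")
        name = p.stem
        if name in ("habitat", "aspect"):
            layers[name] = arr.astype(int)
        else:
            layers[name] = arr
    return LandscapeGrid(x0=ref[0], y0=ref[1], cell_size=ref[2], layers=layers)
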