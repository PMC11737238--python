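"""Gridded landscape container and plain-text raster I/O.

A :class:`LandscapeStack` bundles a categorical land-classification grid with a
set of Euclidean-distance grids (meters to the nearest mapped feature of each
kind).  Grids are stored row 0 = north, like conventional raster files, with
the origin at the lower-left (south-west) corner of the extent.  Cell
membership uses the half-open convention ``x in [left, right)`` horizontally
and ``y in (bottom, top]`` vertically, so a point on the shared edge of two
cells belongs to exactly one of them.

Rasters are read and written as Esri ASCII grids (``.asc``), a plain-text
single-band format understood by QGIS, GDAL and most GIS stacks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Land-classification codes (ESA WorldCover style, 7 classes).
LANDCLASS_NAMES = {
    1: "tree_cover",
    2: "greenland",
    3: "agricultural_field",
    4: "settlement",
    5: "sparse_vegetation",
    6: "water",
    7: "wetland",
}

#: Distance layers carried by a full stack.
DISTANCE_LAYERS = (
    "flowing_waters",
    "protected_areas",
    "district_road",
    "agricultural_road",
    "state_road",
    "federal_highway",
    "railway",
)

#: The three constituents of the "linear anthropogenic structures" covariate.
LINEAR_ANTHROPOGENIC = ("state_road", "federal_highway", "railway")


class RasterSampleError(ValueError):
    """A point fell outside a raster's extent."""


@dataclass
class LandscapeStack:
    """Land-class grid plus distance-to-feature grids over one extent.

    Parameters
    ----------
    landclass
        Integer grid of codes 1-7, row 0 = north.
    distance_layers
        Mapping layer name -> non-negative float grid (meters), row 0 = north.
    origin_x, origin_y
        Coordinates (m) of the lower-left corner of the extent.
    landclass_cell
        Cell size (m) of the land-class grid.  Default 10.
    distance_cell
        Cell size (m) of the distance grids.  Default 1; coarser grids are
        fully supported and are what the synthetic generator produces.
    crs
        Identifier of the shared projected CRS, metadata only.
    """

    landclass: np.ndarray
    distance_layers: dict[str, np.ndarray]
    origin_x: float
    origin_y: float
    landclass_cell: float = 10.0
    distance_cell: float = 1.0
    crs: str = "EPSG:32632"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = np.unique(self.landclass)
        if codes.size and (codes.min() < 1 or codes.max() > 7):
            raise ValueError(f"landclass codes outside 1..7: {codes}")
        for name, grid in self.distance_layers.items():
            if np.any(grid < 0):
                raise ValueError(f"negative distances in layer {name!r}")

    # -- geometry -----------------------------------------------------------

    def _grid_of(self, layer: str) -> tuple[np.ndarray, float]:
        if layer == "landclass":
            return self.landclass, self.landclass_cell
        try:
            return self.distance_layers[layer], self.distance_cell
        except KeyError:
            raise KeyError(f"unknown layer {layer!r}") from None

    def cell_index(self, layer: str, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cells containing points, without bounds checks."""
        grid, cell = self._grid_of(layer)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        nrows = grid.shape[0]
        top = self.origin_y + nrows * cell
        col = np.floor((x - self.origin_x) / cell).astype(int)
        # y == top maps to row 0; each cell owns its top edge, so the grid's
        # bottom edge falls outside
        row = np.floor((top - y) / cell).astype(int)
        return row, col

    def sample(self, layer: str, x, y):
        """Value of ``layer`` at the cell containing each point (no interpolation).

        Raises
        ------
        RasterSampleError
            If any point lies outside the raster extent, naming the layer.
        """
        grid, _ = self._grid_of(layer)
        row, col = self.cell_index(layer, x, y)
        nrows, ncols = grid.shape
        bad = (row < 0) | (row >= nrows) | (col < 0) | (col >= ncols)
        if np.any(bad):
            raise RasterSampleError(
                f"{int(np.sum(bad))} point(s) outside extent of layer {layer!r}"
            )
        out = grid[row, col]
        return out if np.ndim(x) else out.item()

    def inside(self, x, y, layer: str = "landclass") -> np.ndarray:
        grid, _ = self._grid_of(layer)
        row, col = self.cell_index(layer, x, y)
        nrows, ncols = grid.shape
        return (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)

    # -- I/O ----------------------------------------------------------------

    def write(self, outdir: str | Path) -> None:
        """Write one ``.asc`` file per layer plus a JSON sidecar with the CRS."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_ascii_grid(
            outdir / "landclass.asc", self.landclass, self.origin_x,
            self.origin_y, self.landclass_cell, fmt="%d",
        )
        for name, grid in self.distance_layers.items():
            write_ascii_grid(
                outdir / f"dist_{name}.asc", grid, self.origin_x,
                self.origin_y, self.distance_cell, fmt="%.1f",
            )
        sidecar = {"crs": self.crs, "distance_layers": sorted(self.distance_layers)}
        (outdir / "landscape.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read(cls, indir: str | Path) -> "LandscapeStack":
        indir = Path(indir)
        sidecar = json.loads((indir / "landscape.json").read_text())
        lc, x0, y0, cell_lc = read_ascii_grid(indir / "landclass.asc")
        layers = {}
        cell_d = cell_lc
        for name in sidecar["distance_layers"]:
            layers[name], _, _, cell_d = read_ascii_grid(indir / f"dist_{name}.asc")
        return cls(
            landclass=lc.astype(np.int8),
            distance_layers={k: v.astype(np.float32) for k, v in layers.items()},
            origin_x=x0, origin_y=y0,
            landclass_cell=cell_lc, distance_cell=cell_d,
            crs=sidecar["crs"],
        )


def write_ascii_grid(path, grid, xll, yll, cell, fmt="%.3f", nodata=-9999) -> None:
    header = (
        f"ncols {grid.shape[1]}\nnrows {grid.shape[0]}\n"
        f"xllcorner {xll}\nyllcorner {yll}\ncellsize {cell}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid, fmt=fmt)


def read_ascii_grid(path) -> tuple[np.ndarray, float, float, float]:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        grid = np.loadtxt(fh)
    grid = grid.reshape(int(hdr["nrows"]), int(hdr["ncols"]))
    return grid, hdr["xllcorner"], hdr["yllcorner"], hdr["cellsize"]
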