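"""Bathymetry grids: bottom depth on a regular planar raster.

The analysis world is a flat plane in metres (a single fjord system), so a
grid is fully described by its lower-left corner, cell size and a matrix of
bottom depths (positive down).  Grids are stored as ESRI ASCII rasters, a
plain-text format readable by standard GIS tools.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BathymetryGrid", "read_ascii_grid", "write_ascii_grid"]

_NODATA = -9999.0


class BathymetryGrid:
    """Bottom depth (m, positive down) on a regular grid.

    Parameters
    ----------
    depths : (nrows, ncols) array
        Bottom depth per cell; row 0 is the *southernmost* row (smallest y).
    origin : (float, float)
        Planar coordinates (m) of the lower-left corner of the grid.
    cell_size : float
        Cell edge length in metres (default 100, the resolution of modelled
        coastal bathymetry products).
    """

    def __init__(self, depths, origin=(0.0, 0.0), cell_size=100.0):
        depths = np.asarray(depths, dtype=float)
        if depths.ndim != 2:
            raise ValueError("depths must be a 2-D array")
        if cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.depths = depths
        self.origin = (float(origin[0]), float(origin[1]))
        self.cell_size = float(cell_size)

    @property
    def shape(self):
        return self.depths.shape

    @property
    def extent(self):
        """(xmin, xmax, ymin, ymax) of the grid in metres."""
        nr, nc = self.depths.shape
        x0, y0 = self.origin
        return (x0, x0 + nc * self.cell_size, y0, y0 + nr * self.cell_size)

    def contains(self, x, y):
        xmin, xmax, ymin, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def depth_at(self, x, y):
        """Nearest-cell bottom depth at planar position(s) ``x, y``.

        Positions outside the grid return NaN.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        nr, nc = self.depths.shape
        ok = (col >= 0) & (col < nc) & (row >= 0) & (row < nr)
        out = np.full(x.shape, np.nan)
        out[ok] = self.depths[row[ok], col[ok]]
        return out if out.size > 1 else float(out[0])


def write_ascii_grid(grid: BathymetryGrid, path) -> None:
    """Write a grid as an ESRI ASCII raster (text)."""
    nr, nc = grid.depths.shape
    header = (
        f"ncols {nc}\n"
        f"nrows {nr}\n"
        f"xllcorner {grid.origin[0]:.6f}\n"
        f"yllcorner {grid.origin[1]:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {_NODATA}\n"
    )
    body = np.where(np.isfinite(grid.depths), grid.depths, _NODATA)
    with open(path, "w") as fh:
        fh.write(header)
        # ESRI ASCII stores rows north-to-south
        np.savetxt(fh, body[::-1], fmt="%.4f")


def read_ascii_grid(path) -> BathymetryGrid:
    """Read an ESRI ASCII raster written by :func:`write_ascii_grid`."""
    meta = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1].copy()
    nodata = meta.get("nodata_value", _NODATA)
    data[data == nodata] = np.nan
    return BathymetryGrid(
        data,
        origin=(meta["xllcorner"], meta["yllcorner"]),
        cell_size=meta["cellsize"],
    )
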