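"""Raster file I/O: single-band GeoTIFF and a plain-text (ESRI ASCII) format.

GeoTIFFs are written with the standard georeferencing tags
(ModelPixelScale, ModelTiepoint, GDAL_NODATA) on a planar map-unit grid;
no coordinate reference system is attached.  The ASCII grid format is used
for small human-readable fixtures.
"""

from __future__ import annotations

import os

import numpy as np
import tifffile

from .raster import Grid

__all__ = ["read_geotiff", "write_geotiff", "read_ascii_grid", "write_ascii_grid"]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def write_geotiff(path: str | os.PathLike, grid: Grid) -> None:
    """Write a grid as a single-band GeoTIFF with planar georeferencing."""
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(grid.cell_size), float(grid.cell_size), 0.0)),
        # raster point (0,0) pinned to the NW corner in map coordinates
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(grid.origin_x), float(grid.origin_y), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]
    tifffile.imwrite(path, np.asarray(grid.values), extratags=extratags)


def read_geotiff(path: str | os.PathLike) -> Grid:
    """Read a single-band GeoTIFF written by :func:`write_geotiff`."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        scale = tags[_TAG_PIXEL_SCALE].value
        tie = tags[_TAG_TIEPOINT].value
        nodata_tag = tags.get(_TAG_GDAL_NODATA)
        nodata = float(nodata_tag.value) if nodata_tag is not None else -9999.0
    cell_size = float(scale[0])
    # tiepoint maps raster (i, j) to map (x, y); shift back to the outer corner
    origin_x = float(tie[3]) - float(tie[0]) * cell_size
    origin_y = float(tie[4]) + float(tie[1]) * cell_size
    return Grid(values=values, origin_x=origin_x, origin_y=origin_y, cell_size=cell_size, nodata=nodata)


def write_ascii_grid(path: str | os.PathLike, grid: Grid, fmt: str = "%.10g") -> None:
    """Write a grid in the headered ESRI ASCII format (row 0 = north)."""
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x!r}\n"
        f"yllcorner {grid.origin_y - grid.n_rows * grid.cell_size!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, np.asarray(grid.values), fmt=fmt)


def read_ascii_grid(path: str | os.PathLike, dtype=float) -> Grid:
    """Read a headered ESRI ASCII grid."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, dtype=dtype, ndmin=2)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"grid body {values.shape} does not match header ({n_rows}, {n_cols})")
    cell = header["cellsize"]
    return Grid(
        values=values,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
        nodata=header["nodata_value"],
    )
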