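"""Raster container and plain-text grid I/O.

A :class:`ClimateStack` is a set of co-registered climate layers over one
region: a 3-D value array, a shared validity mask, and a geotransform in
geographic (WGS84) degrees.  Grids are written and read as ESRI ASCII
(``.asc``) files, one per layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GeoTransform:
    """Top-left-anchored geotransform for a north-up grid of square cells.

    ``west``/``north`` are the outer corner of cell (0, 0); ``cellsize`` is
    the cell edge in degrees.  Rows run north to south, columns west to east.
    """

    west: float
    north: float
    cellsize: float

    def cell_center(self, row, col):
        """Longitude/latitude of the center of cell (row, col)."""
        lon = self.west + (np.asarray(col) + 0.5) * self.cellsize
        lat = self.north - (np.asarray(row) + 0.5) * self.cellsize
        return lon, lat

    def rowcol(self, lon, lat):
        """Row/column indices of the cells containing the given points."""
        col = np.floor((np.asarray(lon) - self.west) / self.cellsize).astype(int)
        row = np.floor((self.north - np.asarray(lat)) / self.cellsize).astype(int)
        return row, col


@dataclass
class ClimateStack:
    """Co-registered climate layers over one region.

    Attributes
    ----------
    names : list of str
        Layer names, one per leading axis of ``values``.
    values : ndarray, shape (n_layers, nrows, ncols)
        Cell values; entries outside ``mask`` are undefined.
    mask : ndarray of bool, shape (nrows, ncols)
        True where the cell is valid (inside the region / accessible area).
    transform : GeoTransform
    crs : str
        Always geographic WGS84 here.
    """

    names: list[str]
    values: np.ndarray
    mask: np.ndarray
    transform: GeoTransform
    crs: str = "EPSG:4326"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("values must have shape (n_layers, nrows, ncols)")
        if len(self.names) != self.values.shape[0]:
            raise ValueError("one name per layer required")
        if self.mask.shape != self.values.shape[1:]:
            raise ValueError("mask shape must match layer shape")
        if int(self.mask.sum()) < 2:
            raise ValueError("a ClimateStack needs at least 2 valid cells")

    # ------------------------------------------------------------------
    @property
    def n_layers(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def valid_rowcol(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of valid cells, in row-major order."""
        return np.nonzero(self.mask)

    def valid_table(self) -> np.ndarray:
        """Valid-cell values as an (n_valid, n_layers) array."""
        return self.values[:, self.mask].T

    def valid_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Lon/lat of valid-cell centers, aligned with :meth:`valid_table`."""
        rows, cols = self.valid_rowcol()
        return self.transform.cell_center(rows, cols)

    def values_at(self, lon, lat) -> np.ndarray:
        """(n_points, n_layers) climate values at the cells containing points.

        Raises if any point falls outside the grid or on an invalid cell.
        """
        row, col = self.transform.rowcol(lon, lat)
        nrows, ncols = self.shape
        inside = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
        if not np.all(inside):
            raise ValueError("point outside the raster extent")
        if not np.all(self.mask[row, col]):
            raise ValueError("point falls on a nodata cell")
        return self.values[:, row, col].T

    def with_mask(self, mask: np.ndarray) -> "ClimateStack":
        return ClimateStack(list(self.names), self.values.copy(), mask,
                            self.transform, self.crs)


# ----------------------------------------------------------------------
# ESRI ASCII grid I/O

def write_ascii_grid(path, grid: np.ndarray, mask: np.ndarray,
                     transform: GeoTransform) -> None:
    """Write one layer as an ESRI ASCII grid (text)."""
    nrows, ncols = grid.shape
    out = np.where(mask, grid, NODATA)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {transform.west:.10g}\n"
        f"yllcorner {transform.north - nrows * transform.cellsize:.10g}\n"
        f"cellsize {transform.cellsize:.10g}\n"
        f"NODATA_value {NODATA:.10g}\n"
    )
    body = "\n".join(" ".join(f"{v:.10g}" for v in row) for row in out)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, np.ndarray, GeoTransform]:
    """Read an ESRI ASCII grid; returns (values, mask, transform)."""
    lines = Path(path).read_text().splitlines()
    hdr: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"}:
            hdr[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    nrows, ncols = int(hdr["nrows"]), int(hdr["ncols"])
    nodata = hdr.get("nodata_value", NODATA)
    data = np.loadtxt(lines[i:]).reshape(nrows, ncols)
    mask = data != nodata
    cs = hdr["cellsize"]
    tr = GeoTransform(west=hdr["xllcorner"],
                      north=hdr["yllcorner"] + nrows * cs, cellsize=cs)
    return data, mask, tr


def write_stack(stack: ClimateStack, out_dir, prefix: str = "") -> list[Path]:
    """Write every layer of a stack as ``<prefix><name>.asc``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, name in enumerate(stack.names):
        p = out_dir / f"{prefix}{name}.asc"
        write_ascii_grid(p, stack.values[i], stack.mask, stack.transform)
        paths.append(p)
    return paths


def read_stack(paths: Sequence[Path | str],
               names: Iterable[str] | None = None) -> ClimateStack:
    """Read co-registered ASCII grids into one stack.

    The mask is the intersection of per-layer validity.
    """
    paths = [Path(p) for p in paths]
    if names is None:
        names = [p.stem for p in paths]
    layers, masks, tr0 = [], [], None
    for p in paths:
        vals, mask, tr = read_ascii_grid(p)
        if tr0 is None:
            tr0 = tr
        elif (tr.west, tr.north, tr.cellsize) != (tr0.west, tr0.north, tr0.cellsize):
            raise ValueError(f"grid {p} is not co-registered with the first grid")
        layers.append(vals)
        masks.append(mask)
    mask = np.logical_and.reduce(masks)
    return ClimateStack(list(names), np.stack(layers), mask, tr0)
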