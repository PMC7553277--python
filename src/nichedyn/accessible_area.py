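"""Accessible-area (M) delimitation: minimum convex polygon plus buffer.

Each population's accessible area is the convex hull of its occurrence
points dilated by a fixed-width buffer in planar degree space (the field's
customary 1-degree buffer, ~111 km at the equator).  Climate stacks are
masked to it by cell-center membership.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Polygon

from .raster import ClimateStack

__all__ = ["AccessibleArea", "mcp", "buffer", "mask", "build_accessible_area"]


@dataclass(frozen=True)
class AccessibleArea:
    """A population's accessible area: convex hull + buffer."""

    hull: Polygon
    polygon: Polygon
    buffer_deg: float


def mcp(points: np.ndarray) -> Polygon:
    """Minimum convex polygon of (lon, lat) rows.

    Requires at least 3 non-collinear points; every input point lies inside
    or on the boundary of the result.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3:
        raise ValueError("minimum convex polygon needs at least 3 points")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0:
        raise ValueError("degenerate hull: points are collinear")
    return hull


def buffer(polygon: Polygon, width_deg: float = 1.0) -> Polygon:
    """Minkowski dilation by ``width_deg`` degrees (round joins).

    Width 0 is the identity; negative widths are rejected.
    """
    if width_deg < 0:
        raise ValueError("buffer width must be >= 0")
    if width_deg == 0:
        return polygon
    return polygon.buffer(width_deg, quad_segs=64)


def mask(stack: ClimateStack, area: AccessibleArea | Polygon) -> ClimateStack:
    """Mask a stack to cells whose centers fall inside the area polygon.

    Boundary cells count as inside.  Raises if nothing overlaps.
    """
    poly = area.polygon if isinstance(area, AccessibleArea) else area
    rows, cols = np.nonzero(stack.mask)
    lon, lat = stack.transform.cell_center(rows, cols)
    inside = shapely.intersects_xy(poly, lon, lat)
    if not inside.any():
        raise ValueError("accessible area does not overlap the raster extent")
    new_mask = np.zeros_like(stack.mask)
    new_mask[rows[inside], cols[inside]] = True
    return stack.with_mask(new_mask)


def build_accessible_area(points: np.ndarray,
                          buffer_deg: float = 1.0) -> AccessibleArea:
    """Convex hull of occurrence points plus buffer, as one object."""
    hull = mcp(points)
    return AccessibleArea(hull=hull, polygon=buffer(hull, buffer_deg),
                          buffer_deg=buffer_deg)


def write_wkt(area: AccessibleArea | Polygon, path) -> None:
    poly = area.polygon if isinstance(area, AccessibleArea) else area
    with open(path, "w") as fh:
        fh.write(poly.wkt + "\n")


def read_wkt(path) -> Polygon:
    from shapely import wkt as _wkt
    with open(path) as fh:
        return _wkt.loads(fh.read().strip())
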