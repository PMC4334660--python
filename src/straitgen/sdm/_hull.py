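"""Alpha-hull range polygons rasterized as binary layers."""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import Delaunay, QhullError
from shapely import contains_xy
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import unary_union

from ..io_core import Raster


def _circumradius(a, b, c) -> float:
    ab = np.hypot(*(b - a))
    bc = np.hypot(*(c - b))
    ca = np.hypot(*(a - c))
    s = (ab + bc + ca) / 2.0
    area2 = max(s * (s - ab) * (s - bc) * (s - ca), 0.0)
    if area2 == 0:
        return np.inf
    return ab * bc * ca / (4.0 * np.sqrt(area2))


def alpha_shape(points: np.ndarray, alpha: float):
    """Union of Delaunay triangles whose circumradius is at most ``alpha``."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    try:
        tri = Delaunay(pts)
    except (QhullError, ValueError):
        return MultiPoint(pts).convex_hull  # degenerate: point/line
    polys = []
    for simplex in tri.simplices:
        a, b, c = pts[simplex]
        if _circumradius(a, b, c) <= alpha:
            polys.append(Polygon([a, b, c]))
    if not polys:
        return MultiPoint(pts).convex_hull.buffer(0.0)
    return unary_union(polys)


def alpha_hull_layer(points: np.ndarray, alpha: float,
                     template: Raster) -> Raster:
    """Binary raster: 1 inside the alpha hull of the points, else 0.

    A cell also scores 1 when its center lies within half a cell of a
    presence point, so every presence point's own cell is 1.  With fewer
    than 3 points the hull degenerates to the point-buffer cells alone.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if len(pts) == 0:
        raise ValueError("no points for hull layer")
    lon, lat = template.cell_centers()
    grid = np.zeros(lon.shape, dtype=float)
    if len(pts) >= 3:
        shape = alpha_shape(pts, alpha)
        if not shape.is_empty and shape.area > 0:
            grid[contains_xy(shape, lon, lat)] = 1.0
    else:
        warnings.warn("fewer than 3 points; hull layer is point cells only")
    # half-cell buffer around each point (Chebyshev), covers the point's cell
    half = template.cell_size / 2.0 + 1e-12
    for px, py in pts:
        near = (np.abs(lon - px) <= half) & (np.abs(lat - py) <= half)
        grid[near] = 1.0
    return template.copy_with(grid)
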