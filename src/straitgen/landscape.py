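"""Residual genetic-divergence landscapes.

Pipeline: collapse specimens into sites (mean cross-site genetic distances),
triangulate the sites (Delaunay on lon/lat), fit competing distance-decay
regressions and keep the best by R-squared, attribute the residual of each
triangulation edge to its midpoint, and interpolate the residual points onto
a raster with inverse distance weighting.

Geographic distances for the regressions are great-circle km (haversine);
midpoints are arithmetic lon/lat means, matching planar GIS interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import Delaunay, QhullError

from .io_core import LocalityTable, Raster, haversine_km
from .popgen import DistanceMatrix


class LandscapeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Sites
# ---------------------------------------------------------------------------

@dataclass
class Site:
    site_id: str
    lat: float
    lon: float
    members: list[str]


@dataclass
class SiteSet:
    sites: list[Site]
    site_distance: np.ndarray  # mean cross-pair p-distance; diagonal = within

    def coords(self) -> np.ndarray:
        return np.array([[s.lon, s.lat] for s in self.sites])


def collapse_to_sites(dm: DistanceMatrix, loc: LocalityTable,
                      tol: float = 0.0) -> SiteSet:
    """Group specimens into sites and average genetic distances.

    Specimens within ``tol`` degrees of arc of each other (single linkage on
    great-circle separation expressed in degrees) share a site.  Site
    coordinates are member centroids; between-site distance is the mean over
    all cross-site specimen pairs; the diagonal holds the mean within-site
    pairwise distance (0 for singletons).
    """
    ids = dm.ids
    lat = np.array([loc.coords_for(i)[0] for i in ids])
    lon = np.array([loc.coords_for(i)[1] for i in ids])
    n = len(ids)
    # single-linkage clustering via union-find on the tol threshold
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    km_per_deg = 2 * np.pi * 6371.0088 / 360.0
    for i in range(n):
        sep_km = haversine_km(lat[i], lon[i], lat[i + 1:], lon[i + 1:])
        close = np.flatnonzero(sep_km / km_per_deg <= tol) + i + 1
        for j in close:
            ri, rj = find(i), find(int(j))
            if ri != rj:
                parent[rj] = ri

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    members = sorted(groups.values(), key=lambda g: g[0])

    sites = []
    for k, g in enumerate(members):
        sites.append(Site(
            site_id=f"site{k}",
            lat=float(lat[g].mean()),
            lon=float(lon[g].mean()),
            members=[ids[i] for i in g],
        ))
    m = len(sites)
    sd = np.zeros((m, m))
    for a in range(m):
        ga = members[a]
        if len(ga) > 1:
            block = dm.d[np.ix_(ga, ga)]
            iu = np.triu_indices(len(ga), k=1)
            sd[a, a] = float(block[iu].mean())
        for b in range(a + 1, m):
            gb = members[b]
            sd[a, b] = sd[b, a] = float(dm.d[np.ix_(ga, gb)].mean())
    return SiteSet(sites=sites, site_distance=sd)


# ---------------------------------------------------------------------------
# Delaunay triangulation
# ---------------------------------------------------------------------------

def delaunay_edges(sites: SiteSet) -> list[tuple[int, int]]:
    """Unique undirected Delaunay edges over site (lon, lat) coordinates."""
    pts = sites.coords()
    if len(pts) < 3:
        raise LandscapeError(
            "Delaunay triangulation needs >= 3 sites; use direct pairwise mode"
        )
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise LandscapeError(
            "sites are collinear or degenerate; use direct pairwise mode"
        ) from exc
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(i, j), max(i, j)))
    return sorted(edges)


# ---------------------------------------------------------------------------
# Distance-decay regressions
# ---------------------------------------------------------------------------

@dataclass
class DecayModelFit:
    family: str  # linear | log_linear | asymptotic
    params: dict[str, float]
    r_squared: float
    converged: bool = True

    def predict(self, g: np.ndarray) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        p = self.params
        if self.family == "linear":
            return p["a"] + p["b"] * g
        if self.family == "log_linear":
            return p["a"] + p["b"] * np.log(g)
        if self.family == "asymptotic":
            return p["a"] * (1.0 - np.exp(-p["b"] * g))
        raise LandscapeError(f"unknown family {self.family!r}")


def _r_squared(obs: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(((obs - pred) ** 2).sum())
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit_decay_models(genetic: np.ndarray, geographic_km: np.ndarray
                     ) -> tuple[DecayModelFit, list[DecayModelFit]]:
    """Fit linear, log-linear and asymptotic distance-decay models.

    Returns (best fit by R-squared among converged fits, all fits).  The
    asymptotic model ``d = a * (1 - exp(-b*g))`` uses multi-start nonlinear
    least squares with non-negative parameters; non-convergence is recorded
    rather than fatal.
    """
    d = np.asarray(genetic, dtype=float)
    g = np.asarray(geographic_km, dtype=float)
    if d.size < 3:
        raise LandscapeError("need at least 3 (genetic, geographic) pairs")
    if (g <= 0).any():
        raise LandscapeError("geographic distances must be positive")
    fits: list[DecayModelFit] = []

    b, a = np.polyfit(g, d, 1)
    lin = DecayModelFit("linear", {"a": float(a), "b": float(b)},
                        _r_squared(d, a + b * g))
    fits.append(lin)

    b, a = np.polyfit(np.log(g), d, 1)
    loglin = DecayModelFit("log_linear", {"a": float(a), "b": float(b)},
                           _r_squared(d, a + b * np.log(g)))
    fits.append(loglin)

    fits.append(_fit_asymptotic(d, g))

    converged = [f for f in fits if f.converged]
    if not converged:
        raise LandscapeError("no distance-decay model converged")
    best = max(converged, key=lambda f: f.r_squared)
    return best, fits


def _fit_asymptotic(d: np.ndarray, g: np.ndarray) -> DecayModelFit:
    def model(x, a, b):
        return a * (1.0 - np.exp(-b * x))

    starts = [(max(d.max(), 1e-6), 1.0 / g.mean()),
              (max(d.max(), 1e-6), 1.0 / g.max())]
    best: DecayModelFit | None = None
    for a0, b0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(model, g, d, p0=(a0, b0),
                                    bounds=([0, 0], [np.inf, np.inf]),
                                    maxfev=10000)
        except (RuntimeError, ValueError):
            continue
        r2 = _r_squared(d, model(g, *popt))
        fit = DecayModelFit("asymptotic", {"a": float(popt[0]), "b": float(popt[1])},
                            r2, converged=True)
        if best is None or fit.r_squared > best.r_squared:
            best = fit
    if best is None:
        return DecayModelFit("asymptotic", {"a": np.nan, "b": np.nan},
                             -np.inf, converged=False)
    return best


# ---------------------------------------------------------------------------
# Residuals and interpolation
# ---------------------------------------------------------------------------

@dataclass
class ResidualPoint:
    mid_lon: float
    mid_lat: float
    residual: float


@dataclass
class ResidualPointSet:
    points: list[ResidualPoint] = field(default_factory=list)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lon = np.array([p.mid_lon for p in self.points])
        lat = np.array([p.mid_lat for p in self.points])
        val = np.array([p.residual for p in self.points])
        return lon, lat, val


def edge_distances_km(sites: SiteSet, edges) -> np.ndarray:
    out = []
    for i, j in edges:
        si, sj = sites.sites[i], sites.sites[j]
        out.append(float(haversine_km(si.lat, si.lon, sj.lat, sj.lon)))
    return np.array(out)


def edge_residuals(best: DecayModelFit, sites: SiteSet,
                   edges: list[tuple[int, int]]) -> ResidualPointSet:
    """Observed minus predicted genetic distance, placed at edge midpoints."""
    if not best.converged:
        raise LandscapeError("selected decay model did not converge")
    g = edge_distances_km(sites, edges)
    pred = best.predict(g)
    points = []
    for (i, j), p in zip(edges, pred):
        si, sj = sites.sites[i], sites.sites[j]
        points.append(ResidualPoint(
            mid_lon=(si.lon + sj.lon) / 2.0,
            mid_lat=(si.lat + sj.lat) / 2.0,
            residual=float(sites.site_distance[i, j] - p),
        ))
    return ResidualPointSet(points)


def idw_interpolate(points: ResidualPointSet, template: Raster,
                    power: float = 2.0, eps: float = 1e-9) -> Raster:
    """Inverse-distance-weighted interpolation of residuals onto a grid.

    Cell value = sum(w_k v_k) / sum(w_k) with w_k = dist^(-power); a cell
    center within ``eps`` degrees of a data point takes that point's value
    exactly, making the surface honor its inputs.
    """
    if not points.points:
        raise LandscapeError("no residual points to interpolate")
    if power <= 0:
        raise LandscapeError("IDW power must be positive")
    plon, plat, pval = points.arrays()
    lon, lat = template.cell_centers()
    dist = np.sqrt((lon[..., None] - plon) ** 2 + (lat[..., None] - plat) ** 2)
    exact = dist < eps
    dist = np.where(exact, 1.0, dist)
    w = dist ** (-power)
    grid = (w * pval).sum(axis=-1) / w.sum(axis=-1)
    hit = exact.any(axis=-1)
    if hit.any():
        first = exact.argmax(axis=-1)
        grid = np.where(hit, pval[first], grid)
    return template.copy_with(grid)


def residuals_to_csv(path, points: ResidualPointSet) -> None:
    import pandas as pd

    pd.DataFrame(
        [{"mid_lon": p.mid_lon, "mid_lat": p.mid_lat, "residual": p.residual}
         for p in points.points]
    ).to_csv(path, index=False)
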