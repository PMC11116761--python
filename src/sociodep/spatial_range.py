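"""Per-unit spatial extent of depredation events.

Three range metrics are computed from the locations of the vessel
sightings in which each social unit was photographed:

* minimum convex polygon (MCP) area in km^2 and as a percentage of the
  pooled fishing-area MCP (the MCP over all units' sightings);
* occupancy of a 0.1 deg x 0.1 deg lon/lat graticule, in cells and as a
  percentage of the pooled cell count;
* kernel utilisation distribution areas at the 50% and 95% isopleths
  (bivariate Gaussian KDE on equal-area projected coordinates).

Metric areas are computed after projecting coordinates with a spherical
Lambert azimuthal equal-area projection centred on the pooled-data
centroid; grid-cell metrics stay on the lon/lat graticule.  Annual series
use a per-year pooled denominator; cumulative expansion curves (years
since a unit's first sighting) use the whole-period denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import MultiPoint

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


# ---------------------------------------------------------------------------
# Equal-area projection
# ---------------------------------------------------------------------------

@dataclass
class ProjectedPoints:
    """Lon/lat points with their equal-area projected coordinates in km."""

    lon: np.ndarray
    lat: np.ndarray
    x: np.ndarray
    y: np.ndarray
    lon0: float
    lat0: float

    def __len__(self) -> int:
        return self.lon.size


def project_points(lon, lat, center: tuple[float, float] | None = None) -> ProjectedPoints:
    """Spherical Lambert azimuthal equal-area projection (km).

    ``center`` is (lon0, lat0) in degrees; by default the centroid of the
    input.  The projection is exactly area-preserving on the sphere.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    if center is None:
        center = (float(lon.mean()), float(lat.mean()))
    lon0, lat0 = center
    lam, phi = np.radians(lon), np.radians(lat)
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    k = np.sqrt(2.0 / np.maximum(1.0 + c, 1e-12))
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_KM * k * (np.cos(phi0) * np.sin(phi)
                               - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0))
    return ProjectedPoints(lon, lat, x, y, lon0, lat0)


def inverse_project(pp: ProjectedPoints) -> tuple[np.ndarray, np.ndarray]:
    """Recover lon/lat (degrees) from projected km coordinates."""
    x, y = pp.x / EARTH_RADIUS_KM, pp.y / EARTH_RADIUS_KM
    rho = np.hypot(x, y)
    cc = 2.0 * np.arcsin(np.clip(rho / 2.0, -1.0, 1.0))
    lam0, phi0 = np.radians(pp.lon0), np.radians(pp.lat0)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(rho == 0, phi0,
                       np.arcsin(np.clip(np.cos(cc) * np.sin(phi0)
                                         + y * np.sin(cc) * np.cos(phi0) / np.maximum(rho, 1e-300), -1, 1)))
        lam = lam0 + np.arctan2(x * np.sin(cc),
                                rho * np.cos(phi0) * np.cos(cc)
                                - y * np.sin(phi0) * np.sin(cc))
        lam = np.where(rho == 0, lam0, lam)
    return np.degrees(lam), np.degrees(phi)


# ---------------------------------------------------------------------------
# Range metrics
# ---------------------------------------------------------------------------

def mcp_area(pp: ProjectedPoints) -> float:
    """Convex-hull (minimum convex polygon) area in km^2."""
    if len(pp) == 0:
        raise ValueError("no points")
    hull = MultiPoint(list(zip(pp.x, pp.y))).convex_hull
    return float(getattr(hull, "area", 0.0))


def grid_cells(lon, lat, cell_size_deg: float = 0.1) -> set[tuple[int, int]]:
    """Occupied graticule cells, keyed by (floor(lon/c), floor(lat/c))."""
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    ci = np.floor(lon / cell_size_deg).astype(int)
    cj = np.floor(lat / cell_size_deg).astype(int)
    return set(zip(ci.tolist(), cj.tolist()))


def href_bandwidth(pp: ProjectedPoints) -> float:
    """Ad-hoc reference bandwidth for a bivariate Gaussian kernel (km)."""
    n = len(pp)
    sd = np.sqrt(0.5 * (pp.x.var(ddof=1) + pp.y.var(ddof=1)))
    return float(sd * n ** (-1.0 / 6.0))


def kernel_ud(pp: ProjectedPoints, isopleths=(50, 95),
              bandwidth: float | None = None, grid_size: int = 200,
              extend: float = 3.0) -> dict[int, float]:
    """Utilisation-distribution isopleth areas (km^2) from a Gaussian KDE.

    The density is evaluated on a ``grid_size``^2 raster extending
    ``extend`` bandwidths beyond the data bounding box; each isopleth area
    accumulates raster cells in decreasing density order until the stated
    probability mass is enclosed.  Fewer than 5 points is unreliable and
    raises; identical points are degenerate and raise.
    """
    if len(pp) < 5:
        raise ValueError("kernel UD needs at least 5 points")
    if np.allclose(pp.x, pp.x[0]) and np.allclose(pp.y, pp.y[0]):
        raise ValueError("all points identical: kernel UD is degenerate")
    h = href_bandwidth(pp) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    gx = np.linspace(pp.x.min() - extend * h, pp.x.max() + extend * h, grid_size)
    gy = np.linspace(pp.y.min() - extend * h, pp.y.max() + extend * h, grid_size)
    cell_area = (gx[1] - gx[0]) * (gy[1] - gy[0])
    xx, yy = np.meshgrid(gx, gy)
    # isotropic Gaussian kernels, evaluated in chunks to bound memory
    dens = np.zeros(xx.size)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    data = np.column_stack([pp.x, pp.y])
    norm = 1.0 / (2.0 * np.pi * h * h * len(pp))
    for start in range(0, len(pp), 512):
        chunk = data[start:start + 512]
        d2 = ((pts[:, None, :] - chunk[None, :, :]) ** 2).sum(axis=2)
        dens += norm * np.exp(-d2 / (2.0 * h * h)).sum(axis=1)
    order = np.argsort(dens)[::-1]
    mass = np.cumsum(dens[order]) * cell_area
    total = mass[-1]
    out = {}
    for q in isopleths:
        target = q / 100.0 * total
        k = int(np.searchsorted(mass, target)) + 1
        out[int(q)] = float(k * cell_area)
    return out


# ---------------------------------------------------------------------------
# Per-unit summaries
# ---------------------------------------------------------------------------

def unit_sighting_points(ds, partition) -> dict[str, pd.DataFrame]:
    """Vessel-sighting locations per social unit.

    A unit is located at every vessel sighting in which at least one
    member was photographed.  Returns unit -> DataFrame(lon, lat, year).
    """
    from .sightings_io import VESSEL
    out = {}
    for unit, members in partition.units.items():
        mem = set(members)
        rows = [(s.lon, s.lat, s.year) for s in ds.sightings
                if s.platform == VESSEL and s.individual_ids & mem]
        out[unit] = pd.DataFrame(rows, columns=["lon", "lat", "year"])
    return out


def range_proportions(unit_points: Mapping[str, pd.DataFrame],
                      cell_size_deg: float = 0.1,
                      isopleths=(50, 95),
                      grid_size: int = 200
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Range summaries, annual series and cumulative expansion curves.

    Returns ``(summary, annual, cumulative)``:

    * summary — one row per unit: mcp_area_km2, pct_fishing_area_mcp,
      n_cells, pct_fishing_area_cells, ud50_km2, ud95_km2, n_years_sighted.
    * annual — (unit, year, pct_mcp, pct_cells) with per-year pooled
      denominators.
    * cumulative — (unit, years_since_first, pct_mcp, pct_cells) with
      whole-period denominators; curves are non-decreasing and end at the
      unit's all-years percentage.
    """
    pooled = pd.concat([df for df in unit_points.values() if len(df)],
                       ignore_index=True)
    if pooled.empty:
        raise ValueError("pooled point set is empty")
    center = (float(pooled.lon.mean()), float(pooled.lat.mean()))
    pooled_pp = project_points(pooled.lon, pooled.lat, center)
    pooled_mcp = mcp_area(pooled_pp)
    pooled_cells = grid_cells(pooled.lon, pooled.lat, cell_size_deg)
    year_mcp = {}
    year_cells = {}
    for yr, sub in pooled.groupby("year"):
        year_mcp[yr] = mcp_area(project_points(sub.lon, sub.lat, center))
        year_cells[yr] = grid_cells(sub.lon, sub.lat, cell_size_deg)

    sum_rows, annual_rows, cum_rows = [], [], []
    for unit, df in sorted(unit_points.items()):
        if df.empty:
            sum_rows.append(dict(unit_id=unit, n_years_sighted=0, n_sightings=0,
                                 mcp_area_km2=0.0, pct_fishing_area_mcp=0.0,
                                 n_cells=0, pct_fishing_area_cells=0.0,
                                 ud50_km2=float("nan"), ud95_km2=float("nan")))
            continue
        pp = project_points(df.lon, df.lat, center)
        area = mcp_area(pp)
        cells = grid_cells(df.lon, df.lat, cell_size_deg)
        try:
            ud = kernel_ud(pp, isopleths=isopleths, grid_size=grid_size)
        except ValueError:
            ud = {int(q): float("nan") for q in isopleths}
        sum_rows.append(dict(
            unit_id=unit,
            n_years_sighted=df.year.nunique(),
            n_sightings=len(df),
            mcp_area_km2=area,
            pct_fishing_area_mcp=100.0 * area / pooled_mcp if pooled_mcp else 0.0,
            n_cells=len(cells),
            pct_fishing_area_cells=100.0 * len(cells) / len(pooled_cells),
            ud50_km2=ud.get(50, float("nan")),
            ud95_km2=ud.get(95, float("nan")),
        ))
        for yr, sub in df.groupby("year"):
            ym = year_mcp[yr]
            a = mcp_area(project_points(sub.lon, sub.lat, center))
            annual_rows.append(dict(
                unit_id=unit, year=int(yr),
                pct_mcp=100.0 * a / ym if ym > 0 else 0.0,
                pct_cells=100.0 * len(grid_cells(sub.lon, sub.lat, cell_size_deg))
                / len(year_cells[yr]),
            ))
        first = int(df.year.min())
        for k in range(int(df.year.max()) - first + 1):
            sub = df[df.year <= first + k]
            a = mcp_area(project_points(sub.lon, sub.lat, center))
            cum_rows.append(dict(
                unit_id=unit, years_since_first=k,
                pct_mcp=100.0 * a / pooled_mcp if pooled_mcp else 0.0,
                pct_cells=100.0 * len(grid_cells(sub.lon, sub.lat, cell_size_deg))
                / len(pooled_cells),
            ))
    summary = pd.DataFrame(sum_rows)
    summary.attrs["fishing_area_mcp_km2"] = pooled_mcp
    summary.attrs["fishing_area_n_cells"] = len(pooled_cells)
    return summary, pd.DataFrame(annual_rows), pd.DataFrame(cum_rows)


def spearman_range_vs_years(summary: pd.DataFrame,
                            metrics=("mcp_area_km2", "ud95_km2", "ud50_km2",
                                     "n_cells")) -> pd.DataFrame:
    """Spearman rank correlation of each range metric with years sighted."""
    if len(summary) < 4:
        raise ValueError("need at least 4 units")
    years = summary["n_years_sighted"].to_numpy(dtype=float)
    rows = []
    for m in metrics:
        v = summary[m].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        if years[ok].std() == 0 or v[ok].std() == 0:
            rows.append(dict(metric=m, rho=float("nan"), p_value=float("nan"),
                             flagged="zero variance"))
            continue
        rho, p = stats.spearmanr(years[ok], v[ok])
        rows.append(dict(metric=m, rho=float(rho), p_value=float(p), flagged=""))
    return pd.DataFrame(rows)
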