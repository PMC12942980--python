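"""Hexagonal land tessellation and per-hexagon aggregation.

The grid is a flat-topped hexagon lattice laid out in an equal-area
projection (cylindrical equal-area by default) and clipped to the land
polygons, so every cell fragment keeps its true area in km^2.  Hexagon
size is set by the circumradius (center-to-vertex distance); an unclipped
cell has area (3*sqrt(3)/2) r^2.  Points and raster cells are assigned to
hexagons by containment, with boundary ties broken toward the lowest
cell id so every object lands in exactly one hexagon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import xarray as xr
from shapely.strtree import STRtree

from . import grids
from .grids import CylindricalEqualArea


@dataclass
class HexGrid:
    cells: pd.DataFrame          # hex_id, geometry (projected km), area_km2, lon, lat
    projection: CylindricalEqualArea
    circumradius_km: float

    def __len__(self):
        return len(self.cells)

    @property
    def tree(self) -> STRtree:
        if not hasattr(self, "_tree"):
            self._tree = STRtree(self.cells["geometry"].tolist())
        return self._tree


def _hex_polygon(cx: float, cy: float, r: float) -> shapely.Polygon:
    ang = np.deg2rad(np.arange(0, 360, 60))  # flat-topped: vertex at 0 deg
    return shapely.Polygon(np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)]))


def build_grid(land, circumradius_km: float,
               projection: CylindricalEqualArea | None = None) -> HexGrid:
    """Clip a flat-topped hexagon lattice to the land polygons.

    ``land`` is a shapely (multi)polygon in lon/lat.  Cells fully offshore
    are dropped; fragments keep their clipped geometry and true area.
    """
    if circumradius_km <= 0:
        raise ValueError("circumradius must be positive")
    if land.is_empty:
        return HexGrid(
            cells=pd.DataFrame(columns=["hex_id", "geometry", "area_km2", "lon", "lat"]),
            projection=projection or CylindricalEqualArea(),
            circumradius_km=circumradius_km,
        )
    if projection is None:
        mid_lat = float(np.mean(shapely.bounds(land)[[1, 3]]))
        projection = CylindricalEqualArea(standard_parallel=mid_lat)
    land_xy = projection.transform_geom(land)
    x0, y0, x1, y1 = shapely.bounds(land_xy)
    r = float(circumradius_km)
    dx, dy = 1.5 * r, np.sqrt(3.0) * r

    cols = np.arange(int(np.floor((x0 - r) / dx)), int(np.ceil((x1 + r) / dx)) + 1)
    rows_ = np.arange(int(np.floor((y0 - dy) / dy)), int(np.ceil((y1 + dy) / dy)) + 1)
    centers = [
        (c * dx, rr * dy + (abs(c) % 2) * dy / 2)
        for rr in rows_ for c in cols
    ]
    hexes = [_hex_polygon(cx, cy, r) for cx, cy in centers]
    clipped = shapely.intersection(np.array(hexes, dtype=object), land_xy)
    keep = ~shapely.is_empty(clipped)
    geoms = [g for g, k in zip(clipped, keep) if k]
    areas = shapely.area(np.array(geoms, dtype=object))
    cent = shapely.centroid(np.array(geoms, dtype=object))
    lon, lat = projection.inverse(shapely.get_x(cent), shapely.get_y(cent))
    cells = pd.DataFrame({
        "hex_id": np.arange(len(geoms)),
        "geometry": geoms,
        "area_km2": areas,
        "lon": lon,
        "lat": lat,
    })
    return HexGrid(cells=cells, projection=projection, circumradius_km=r)


def _assign_xy(grid: HexGrid, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Hex id per projected point (lowest id wins on boundaries; -1 if none)."""
    pts = shapely.points(x, y)
    out = np.full(len(pts), -1, dtype=np.int64)
    idx_pt, idx_hex = grid.tree.query(pts, predicate="intersects")
    ids = grid.cells["hex_id"].to_numpy()
    order = np.argsort(-ids[idx_hex])  # apply highest first so lowest id wins
    out[idx_pt[order]] = ids[idx_hex[order]]
    return out


def assign_points(records: pd.DataFrame, grid: HexGrid) -> pd.DataFrame:
    """Annotate records with the containing hexagon id (-1 when outside)."""
    x, y = grid.projection.forward(records["lon"].to_numpy(), records["lat"].to_numpy())
    out = records.copy()
    out["hex_id"] = _assign_xy(grid, x, y)
    return out


def density_and_richness(assigned: pd.DataFrame, grid: HexGrid) -> pd.DataFrame:
    """Per-hexagon record density (records/km^2) and species richness.

    Richness is the count of distinct species; an area-normalized variant
    (species per km^2) is stored alongside, mirroring the area weighting
    of the density measure.  Hexagons without records report zeros.
    """
    inside = assigned[assigned["hex_id"] >= 0]
    n = inside.groupby("hex_id").size()
    rich = inside.groupby("hex_id")["species"].nunique()
    out = grid.cells[["hex_id", "area_km2", "lon", "lat"]].copy()
    out["n_records"] = out["hex_id"].map(n).fillna(0).astype(int)
    out["record_density"] = out["n_records"] / out["area_km2"]
    out["richness"] = out["hex_id"].map(rich).fillna(0).astype(int)
    out["richness_per_km2"] = out["richness"] / out["area_km2"]
    return out


def raster_cell_assignment(da: xr.DataArray, grid: HexGrid) -> pd.DataFrame:
    """Map every finite raster cell (by center) to its hexagon.

    Returns a frame (row, col, hex_id, value-independent) reusable across
    rasters sharing the grid.
    """
    lon, lat = np.meshgrid(da["lon"].values, da["lat"].values)
    x, y = grid.projection.forward(lon.ravel(), lat.ravel())
    hex_id = _assign_xy(grid, x, y)
    rows, cols = np.meshgrid(np.arange(da["lat"].size), np.arange(da["lon"].size),
                             indexing="ij")
    return pd.DataFrame({
        "row": rows.ravel(), "col": cols.ravel(), "hex_id": hex_id,
    })


def zonal_stats(da: xr.DataArray, grid: HexGrid, statistic: str = "mean",
                assignment: pd.DataFrame | None = None) -> pd.Series:
    """Per-hexagon mean, sum, or mode of a raster.

    NaN raster cells are ignored; hexagons with no finite cell get NaN
    (mean/mode) or 0 (sum).  Pass a cached ``assignment`` from
    :func:`raster_cell_assignment` to amortize the point-in-polygon work.
    """
    if statistic not in {"mean", "sum", "mode"}:
        raise ValueError(f"unknown statistic {statistic!r}")
    if assignment is None:
        assignment = raster_cell_assignment(da, grid)
    vals = da.values[assignment["row"].to_numpy(), assignment["col"].to_numpy()]
    df = pd.DataFrame({"hex_id": assignment["hex_id"].to_numpy(), "value": vals})
    df = df[(df["hex_id"] >= 0) & np.isfinite(df["value"])]
    if statistic == "mean":
        agg = df.groupby("hex_id")["value"].mean()
    elif statistic == "sum":
        agg = df.groupby("hex_id")["value"].sum()
    else:
        agg = df.groupby("hex_id")["value"].agg(
            lambda v: v.value_counts().sort_index().idxmax()
        )
    fill = 0.0 if statistic == "sum" else np.nan
    return agg.reindex(grid.cells["hex_id"], fill_value=fill).rename(da.name or "value")
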