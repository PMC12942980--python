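"""Raster containers and the equal-area projection used for hexagon work.

Rasters throughout the package are :class:`xarray.DataArray` objects on a
regular geographic (lon/lat, WGS84) grid, with cell-center coordinates on
dims ``("lat", "lon")``; monthly temperature stacks add a leading
``"month"`` dim (1..12).  Ocean / no-data is NaN.
"""

from __future__ import annotations

import numpy as np
import shapely
import xarray as xr

EARTH_RADIUS_KM = 6371.0088

Extent = tuple[float, float, float, float]  # lon_min, lat_min, lon_max, lat_max


def grid_coords(extent: Extent, resolution: float) -> tuple[np.ndarray, np.ndarray]:
    """Cell-center lon and lat vectors for a regular grid over ``extent``."""
    lon_min, lat_min, lon_max, lat_max = extent
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    if lon_max <= lon_min or lat_max <= lat_min:
        raise ValueError(f"empty extent {extent}")
    lons = np.arange(lon_min + resolution / 2, lon_max, resolution)
    lats = np.arange(lat_min + resolution / 2, lat_max, resolution)
    return lons, lats


def raster(values, lons, lats, name: str | None = None) -> xr.DataArray:
    """Wrap a 2-D array as a (lat, lon) DataArray."""
    return xr.DataArray(
        np.asarray(values, dtype=float),
        coords={"lat": np.asarray(lats), "lon": np.asarray(lons)},
        dims=("lat", "lon"),
        name=name,
    )


def monthly_raster(values, lons, lats, name: str | None = None) -> xr.DataArray:
    """Wrap a (12, lat, lon) array as a monthly DataArray."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != 12:
        raise ValueError(f"expected 12 monthly layers, got {values.shape[0]}")
    return xr.DataArray(
        values,
        coords={"month": np.arange(1, 13), "lat": np.asarray(lats), "lon": np.asarray(lons)},
        dims=("month", "lat", "lon"),
        name=name,
    )


def resolution_of(da: xr.DataArray) -> tuple[float, float]:
    lon = da["lon"].values
    lat = da["lat"].values
    return float(lon[1] - lon[0]), float(lat[1] - lat[0])


def point_indices(da: xr.DataArray, lons, lats):
    """(row, col, inside) of the cell containing each point; -1 outside."""
    glon = da["lon"].values
    glat = da["lat"].values
    rlon, rlat = resolution_of(da)
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    col = np.floor((lons - (glon[0] - rlon / 2)) / rlon).astype(int)
    row = np.floor((lats - (glat[0] - rlat / 2)) / rlat).astype(int)
    inside = (col >= 0) & (col < glon.size) & (row >= 0) & (row < glat.size)
    return np.where(inside, row, -1), np.where(inside, col, -1), inside


def sample(da: xr.DataArray, lons, lats, fill=np.nan):
    """Value of the containing cell per point; ``fill`` outside the extent.

    Returns ``(values, inside)``; works for 2-D (lat, lon) rasters.
    """
    row, col, inside = point_indices(da, lons, lats)
    out = np.full(row.shape, fill, dtype=float)
    vals = da.values
    out[inside] = vals[row[inside], col[inside]]
    return out, inside


def cell_areas_km2(da: xr.DataArray) -> xr.DataArray:
    """True spherical area of each cell, km^2 (depends on latitude only)."""
    rlon, rlat = resolution_of(da)
    lat = np.deg2rad(da["lat"].values)
    half = np.deg2rad(rlat) / 2
    band = EARTH_RADIUS_KM**2 * np.deg2rad(rlon) * (np.sin(lat + half) - np.sin(lat - half))
    areas = np.repeat(band[:, None], da["lon"].size, axis=1)
    return raster(areas, da["lon"].values, da["lat"].values, name="cell_area_km2")


class CylindricalEqualArea:
    """Lambert cylindrical equal-area projection (km units).

    x = R cos(phi_s) * lambda,  y = R sin(phi) / cos(phi_s), with standard
    parallel ``phi_s``.  Area-true everywhere, which is all the hexagon
    accounting needs; shape distortion away from phi_s is irrelevant to it.
    """

    def __init__(self, standard_parallel: float = 30.0, lon_origin: float = 0.0):
        self.standard_parallel = float(standard_parallel)
        self.lon_origin = float(lon_origin)
        self._k = np.cos(np.deg2rad(self.standard_parallel))
        if self._k <= 0:
            raise ValueError("standard parallel must lie strictly between -90 and 90")

    def forward(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x = EARTH_RADIUS_KM * self._k * np.deg2rad(lon - self.lon_origin)
        y = EARTH_RADIUS_KM * np.sin(np.deg2rad(lat)) / self._k
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lon = np.rad2deg(x / (EARTH_RADIUS_KM * self._k)) + self.lon_origin
        lat = np.rad2deg(np.arcsin(np.clip(y * self._k / EARTH_RADIUS_KM, -1, 1)))
        return lon, lat

    def transform_geom(self, geom):
        """Project a shapely geometry from lon/lat to x/y (km)."""
        def _f(coords):
            x, y = self.forward(coords[:, 0], coords[:, 1])
            return np.column_stack([x, y])

        return shapely.transform(geom, _f)

    def inverse_geom(self, geom):
        def _f(coords):
            lon, lat = self.inverse(coords[:, 0], coords[:, 1])
            return np.column_stack([lon, lat])

        return shapely.transform(geom, _f)
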