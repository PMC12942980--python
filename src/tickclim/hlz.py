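"""Holdridge life-zone (HLZ) climate classification.

The Holdridge system summarizes climate into discrete bioclimatic zones
from three quantities:

* **biotemperature** — the annual mean of monthly temperatures after
  clamping each month into the 0-30 degC range within which plant
  metabolism operates;
* **annual precipitation** (mm);
* the **potential evapotranspiration (PET) ratio** — annual PET divided
  by annual precipitation, with annual PET taken as 58.93 mm per degC of
  biotemperature (the standard Holdridge constant).  Values above 1 mean
  atmospheric demand exceeds supply (dry climates), below 1 humid ones.

Zones are arranged on the classical triangular chart: log2 bands of
biotemperature (boundaries 1.5, 3, 6, 12, 24 degC) crossed with log2
bands of precipitation (boundaries 62.5 * 2^k mm); the PET band is then
implied, since only two of the three axes are independent.  A frost-line
sub-split at 12*sqrt(2) ~ 16.97 degC separates warm temperate from
subtropical zones, bringing the enumeration to the classical 38 classes.
The id -> name table ships as an editable CSV (``data/hlz_zones.csv``) so
the numbering can be re-aligned to any external zone raster; nothing in
the classifier hard-codes ids.

All band intervals are half-open ``[low, high)``; the top biotemperature
and precipitation bands are unbounded above (biotemperature itself is
capped at 30 by construction).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import xarray as xr

from . import grids

#: Annual PET per degree of biotemperature (mm / yr / degC), standard Holdridge.
PET_PER_DEGREE = 58.93

#: Frost line / critical temperature proxy: log2 midpoint of the 12-24 band.
FROST_LINE_BT = 12.0 * np.sqrt(2.0)

NODATA_ID = 0


def biotemperature(monthly_temps, axis: int = 0):
    """Annual biotemperature from 12 monthly mean temperatures (degC).

    Each month is clamped to [0, 30] before averaging.  ``monthly_temps``
    may be a 12-vector or a (12, ...) stack; ``axis`` names the month axis.
    """
    t = np.asarray(monthly_temps, dtype=float)
    if t.shape[axis] != 12:
        raise ValueError(f"expected 12 monthly values along axis {axis}, got {t.shape[axis]}")
    return np.clip(t, 0.0, 30.0).mean(axis=axis)


def pet_ratio(biotemp, precip):
    """Potential-evapotranspiration ratio: 58.93 * biotemperature / precipitation.

    Non-positive precipitation is a domain error; NaN (ocean / no-data)
    propagates quietly.
    """
    bt = np.asarray(biotemp, dtype=float)
    p = np.asarray(precip, dtype=float)
    if np.any(p[np.isfinite(p)] <= 0):
        raise ValueError("precipitation must be strictly positive")
    return PET_PER_DEGREE * bt / p


def load_zone_table(path=None, frost_split: bool = True) -> pd.DataFrame:
    """Load the id/name/band zone table (the default ships with the package).

    With ``frost_split=False`` the subtropical rows are merged into their
    warm temperate counterparts (same humidity province), leaving 31 classes.
    """
    if path is None:
        with resources.as_file(resources.files("tickclim") / "data/hlz_zones.csv") as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    required = {"id", "name", "bt_low", "bt_high", "p_low", "p_high"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"zone table missing columns: {sorted(missing)}")
    if table["id"].duplicated().any():
        raise ValueError("zone ids must be unique")
    if not frost_split and "belt" in table.columns:
        sub = table["belt"] == "subtropical"
        warm = table["belt"] == "warm temperate"
        table.loc[warm, "bt_high"] = float(table.loc[sub, "bt_high"].max())
        table = table.loc[~sub].reset_index(drop=True)
    return table


def classify(biotemp, precip, zone_table: pd.DataFrame | None = None):
    """HLZ id for (biotemperature, precipitation); vectorized, total.

    Every finite (bt in [0, 30], precip > 0) pair receives exactly one id;
    NaN in either input yields :data:`NODATA_ID`.
    """
    if zone_table is None:
        zone_table = load_zone_table()
    bt = np.asarray(biotemp, dtype=float)
    p = np.asarray(precip, dtype=float)
    out = np.zeros(np.broadcast(bt, p).shape, dtype=np.int64)
    bt, p = np.broadcast_arrays(bt, p)
    valid = np.isfinite(bt) & np.isfinite(p)
    for row in zone_table.itertuples(index=False):
        m = (
            valid
            & (bt >= row.bt_low)
            & (bt < row.bt_high)
            & (p >= row.p_low)
            & (p < row.p_high)
        )
        out[m] = row.id
    if np.any(valid & (out == NODATA_ID)):
        raise ValueError("zone table does not cover the full valid climate domain")
    return out if out.ndim else int(out)


def classify_raster(monthly_temp: xr.DataArray, precip: xr.DataArray,
                    zone_table: pd.DataFrame | None = None) -> xr.DataArray:
    """Cellwise HLZ classification of a (12, lat, lon) temperature stack.

    Ocean / no-data cells (NaN in any input) carry id 0.
    """
    bt = biotemperature(monthly_temp.values, axis=0)
    p = precip.values
    ids = classify(np.where(np.isfinite(p), bt, np.nan), p, zone_table)
    da = grids.raster(ids, precip["lon"].values, precip["lat"].values, name="hlz")
    return da.astype(np.int64)


def climate_triple_rasters(monthly_temp: xr.DataArray, precip: xr.DataArray):
    """(biotemperature, precipitation, PET-ratio) rasters from monthly climate."""
    lons, lats = precip["lon"].values, precip["lat"].values
    bt = grids.raster(biotemperature(monthly_temp.values, axis=0), lons, lats, "biotemperature")
    bt = bt.where(np.isfinite(precip.values))
    pr = precip.rename("precipitation")
    pet = grids.raster(
        np.where(np.isfinite(precip.values), PET_PER_DEGREE * bt.values / precip.values, np.nan),
        lons, lats, "pet_ratio",
    )
    return bt, pr, pet


def extract_climate(records: pd.DataFrame, monthly_temp: xr.DataArray,
                    precip: xr.DataArray, zone_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Annotate records with the climate triple and HLZ id of their cell.

    Points outside the raster extent (or over no-data cells) are kept and
    flagged ``in_extent=False`` with NaN climate, never dropped.
    """
    out = records.copy()
    bt, pr, pet = climate_triple_rasters(monthly_temp, precip)
    btv, inside = grids.sample(bt, out["lon"].values, out["lat"].values)
    prv, _ = grids.sample(pr, out["lon"].values, out["lat"].values)
    petv, _ = grids.sample(pet, out["lon"].values, out["lat"].values)
    ok = inside & np.isfinite(btv) & np.isfinite(prv)
    out["biotemperature"] = btv
    out["precipitation"] = prv
    out["pet_ratio"] = petv
    out["in_extent"] = ok
    ids = np.zeros(len(out), dtype=np.int64)
    if ok.any():
        ids[ok] = classify(btv[ok], prv[ok], zone_table)
    out["hlz"] = ids
    return out
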