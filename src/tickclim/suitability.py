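"""Baseline climate suitability and the hybrid zone-mean transfer.

Projection works in two steps.  First, a baseline (current-climate)
suitability surface ``p_i(x)`` in [0, 1] is estimated per genus *i* from
its occurrence records: a product-Gaussian kernel density over the
standardized (biotemperature, precipitation, PET-ratio) triple of the
records, evaluated at every land cell's climate and divided by its
maximum so the modal climate maps to 1.  The kernel uses per-axis
Scott-rule bandwidths (a diagonal kernel: the three axes are functionally
dependent, so a full-covariance density would be ill-conditioned).  The
kernel construction is a stand-in for whatever suitability model a user
prefers — any map in [0, 1] registered to the life-zone raster can enter
step two.

Second, the genus-zone matrix ``m[i, z] = mean over cells of zone z of
p_i`` condenses the baseline into an expected probability of occurrence
of genus *i* in life zone *z*; future suitability is then the pure lookup
of ``m[i, z']`` on the future zone raster, under the assumption that
genera track their climatic niches as the zones move.  Derived surfaces:
expected richness (sum of genus suitabilities), probabilities of at least
one and of more than one genus (independent-Bernoulli composition), and
the change map with its "> +0.2 suitability" gain mask.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr

from . import grids
from .niche_stats import CLIMATE_AXES


def baseline_suitability(records: pd.DataFrame, climate_rasters, bandwidth=None,
                         group_col: str = "genus") -> dict[str, xr.DataArray]:
    """Max-normalized kernel suitability map per genus.

    ``records`` must carry the climate-triple columns; ``climate_rasters``
    is the (biotemperature, precipitation, pet_ratio) raster tuple.
    ``bandwidth`` optionally overrides the per-axis Scott factors with a
    single multiplier on the per-axis record standard deviations.
    """
    if bandwidth is not None and bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    bt, pr, pet = climate_rasters
    cell_climate = np.stack([bt.values, pr.values, pet.values])  # (3, lat, lon)
    land = np.all(np.isfinite(cell_climate), axis=0)
    cells = cell_climate[:, land].T                               # (n_land, 3)

    out: dict[str, xr.DataArray] = {}
    for genus, sub in records.groupby(group_col):
        pts = sub.loc[:, list(CLIMATE_AXES)].to_numpy(dtype=float)
        pts = pts[np.all(np.isfinite(pts), axis=1)]
        if len(pts) == 0:
            raise ValueError(f"genus {genus!r} has no records with climate")
        sd = pts.std(axis=0, ddof=0)
        fallback = cells.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, np.where(fallback > 0, 0.05 * fallback, 1.0))
        factor = bandwidth if bandwidth is not None else len(pts) ** (-1.0 / 7.0)
        h = sd * factor                                           # Scott, d=3
        z_cells = cells / h
        z_pts = pts / h
        d2 = (
            (z_cells**2).sum(axis=1)[:, None]
            - 2 * z_cells @ z_pts.T
            + (z_pts**2).sum(axis=1)[None, :]
        )
        dens = np.exp(-0.5 * np.maximum(d2, 0.0)).mean(axis=1)
        grid = np.full(land.shape, np.nan)
        grid[land] = dens / dens.max()
        out[str(genus)] = grids.raster(grid, bt["lon"].values, bt["lat"].values,
                                       name=f"suitability_{genus}")
    return out


def genus_zone_means(suitability: dict[str, xr.DataArray], hlz_baseline: xr.DataArray,
                     zone_ids=None) -> pd.DataFrame:
    """m[i, z]: per-zone mean baseline suitability, with support counts.

    Returns a tidy frame (genus, zone, m, n_cells); zones listed in
    ``zone_ids`` but absent from the baseline get NaN m and n_cells 0.
    """
    ids = hlz_baseline.values
    present = np.unique(ids[ids > 0])
    if zone_ids is None:
        zone_ids = present
    rows = []
    for genus, da in suitability.items():
        if da.shape != hlz_baseline.shape:
            raise ValueError("suitability and HLZ rasters are on different grids")
        vals = da.values
        for z in zone_ids:
            cells = (ids == z) & np.isfinite(vals)
            n = int(cells.sum())
            rows.append({
                "genus": genus, "zone": int(z),
                "m": float(vals[cells].mean()) if n else np.nan,
                "n_cells": n,
            })
    return pd.DataFrame(rows)


def project(m: pd.DataFrame, hlz_future: xr.DataArray, genus: str,
            fill: float = 0.0) -> xr.DataArray:
    """Fill each future-zone cell with the genus's zone-mean suitability.

    Cells of zones unsupported in the baseline (no m value) receive
    ``fill`` with a warning; ocean (id 0) stays no-data.
    """
    sub = m.loc[(m["genus"] == genus) & m["m"].notna()]
    lookup = dict(zip(sub["zone"].astype(int), sub["m"].astype(float)))
    ids = hlz_future.values
    out = np.full(ids.shape, np.nan)
    land = ids > 0
    out[land] = fill
    unsupported = set(np.unique(ids[land])) - set(lookup)
    if unsupported:
        warnings.warn(
            f"zones {sorted(int(z) for z in unsupported)} unsupported in baseline for "
            f"{genus!r}; filled with {fill}", stacklevel=2,
        )
    for z, v in lookup.items():
        out[ids == z] = v
    return grids.raster(out, hlz_future["lon"].values, hlz_future["lat"].values,
                        name=f"suitability_{genus}")


def expected_richness(maps: dict[str, xr.DataArray] | list[xr.DataArray]) -> xr.DataArray:
    """Cellwise sum of genus suitabilities (expected number of genera)."""
    das = list(maps.values()) if isinstance(maps, dict) else list(maps)
    out = das[0].copy(deep=True)
    out.values[:] = np.sum([d.values for d in das], axis=0)
    return out.rename("expected_richness")


def prob_multi_genus(maps: dict[str, xr.DataArray] | list[xr.DataArray]):
    """P(at least one genus) and P(more than one genus), cells independent Bernoulli.

    P(>=1) = 1 - prod(1 - p_i);  P(>1) = P(>=1) - sum_i p_i prod_{j!=i}(1 - p_j).
    """
    das = list(maps.values()) if isinstance(maps, dict) else list(maps)
    p = np.stack([d.values for d in das])          # (genera, lat, lon)
    q = 1.0 - p
    none = q.prod(axis=0)
    p_any = 1.0 - none
    # P(exactly one): sum_i p_i * prod_{j != i} q_j, stable via masked product
    exactly_one = np.zeros_like(none)
    for i in range(p.shape[0]):
        others = np.delete(q, i, axis=0).prod(axis=0) if p.shape[0] > 1 else np.ones_like(none)
        exactly_one += p[i] * others
    p_multi = p_any - exactly_one
    template = das[0]
    lons, lats = template["lon"].values, template["lat"].values
    return (
        grids.raster(p_any, lons, lats, name="p_at_least_one"),
        grids.raster(np.clip(p_multi, 0.0, 1.0), lons, lats, name="p_more_than_one"),
    )


def change_map(base: xr.DataArray, future: xr.DataArray, threshold: float = 0.2):
    """Suitability change and the strict "> threshold absolute gain" mask."""
    delta = (future - base).rename("delta")
    mask = (delta > threshold) & np.isfinite(delta)
    return delta, mask.rename("gain_mask")
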