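"""High-level composition of the analysis stages.

Thin orchestration over the per-stage modules so the numbered analysis
drivers and the acceptance script share one code path: world generation,
cleaning, life-zone annotation, hexagon accounting, indicator and MANOVA
statistics, zone-mean projection across time slices, and exposure
indices.  Every function takes and returns plain package objects; no
hidden state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from . import hexgrid, hlz, impact, niche_stats, records_qc, suitability, synthetic

DEFAULT_HEX_RADIUS_KM = 60.0


@dataclass
class PipelineResult:
    world: synthetic.SyntheticWorld
    qc: records_qc.QCResult
    records: pd.DataFrame                       # clean, climate-annotated, hex-assigned
    grid: hexgrid.HexGrid
    hlz_rasters: dict[int, xr.DataArray]
    dominant_hlz: pd.Series
    indval: pd.DataFrame
    manova: niche_stats.ManovaResult
    genus_summary: pd.DataFrame
    suitability_maps: dict[str, xr.DataArray]
    zone_matrix: pd.DataFrame
    projections: dict[int, dict[str, xr.DataArray]]
    impact_tables: pd.DataFrame = field(default=None)
    country_change: pd.DataFrame = field(default=None)
    lat_profile: pd.DataFrame = field(default=None)
    livestock_shares: pd.DataFrame = field(default=None)


def species_genus_map(records: pd.DataFrame) -> dict[str, str]:
    return dict(zip(records["species"], records["genus"]))


def classify_slices(world: synthetic.SyntheticWorld) -> dict[int, xr.DataArray]:
    return {
        sl: hlz.classify_raster(c["monthly_temp"], c["precip"])
        for sl, c in world.climate.items()
    }


def clean_and_annotate(world: synthetic.SyntheticWorld,
                       min_records: int = 200) -> tuple[records_qc.QCResult, pd.DataFrame]:
    res = records_qc.run_qc(world.occurrences, land=world.land,
                            min_records=min_records)
    base = world.climate[world.slices[0]]
    rec = hlz.extract_climate(res.clean, base["monthly_temp"], base["precip"])
    return res, rec


def hexagon_stage(world: synthetic.SyntheticWorld, records: pd.DataFrame,
                  hlz_baseline: xr.DataArray,
                  radius_km: float = DEFAULT_HEX_RADIUS_KM):
    grid = hexgrid.build_grid(world.land, circumradius_km=radius_km)
    rec = hexgrid.assign_points(records, grid)
    assign = hexgrid.raster_cell_assignment(hlz_baseline, grid)
    dominant = hexgrid.zonal_stats(hlz_baseline.where(hlz_baseline > 0), grid,
                                   "mode", assignment=assign)
    return grid, rec, assign, dominant


def per_hex_genus_suitability(maps: dict[str, xr.DataArray], grid: hexgrid.HexGrid,
                              assignment: pd.DataFrame) -> pd.DataFrame:
    """Tidy (hex_id, genus, suitability) table of per-hexagon means."""
    parts = []
    for genus, da in maps.items():
        z = hexgrid.zonal_stats(da, grid, "mean", assignment=assignment)
        parts.append(pd.DataFrame({
            "hex_id": z.index, "genus": genus, "suitability": z.to_numpy(),
        }))
    out = pd.concat(parts, ignore_index=True)
    out["suitability"] = out["suitability"].fillna(0.0)
    return out


def species_suitability_table(genus_suit: pd.DataFrame,
                              species_of: dict[str, str],
                              host_of: dict[str, str],
                              host_class: str) -> pd.DataFrame:
    """Expand genus-level suitability to the species of one host class."""
    rows = []
    for species, genus in species_of.items():
        if host_of.get(species) != host_class:
            continue
        sub = genus_suit[genus_suit["genus"] == genus]
        rows.append(pd.DataFrame({
            "hex_id": sub["hex_id"],
            "species": species,
            "suitability": sub["suitability"],
        }))
    if not rows:
        raise ValueError(f"no species with host class {host_class!r}")
    return pd.concat(rows, ignore_index=True)


def run_pipeline(seed: int = 1, n_perm: int = 999,
                 hex_radius_km: float = DEFAULT_HEX_RADIUS_KM,
                 tau: float = impact.DEFAULT_TAU,
                 min_records: int = 200,
                 with_impact: bool = True) -> PipelineResult:
    """The full synthetic-world analysis, end to end, from one seed."""
    world = synthetic.make_world(seed=seed)
    qc_res, rec = clean_and_annotate(world, min_records=min_records)
    rasters = classify_slices(world)
    baseline = rasters[world.slices[0]]
    grid, rec, assignment, dominant = hexagon_stage(world, rec, baseline,
                                                    hex_radius_km)

    matrix = niche_stats.build_matrix(rec, site_zones=dominant.dropna().astype(int))
    indval = niche_stats.indval_test(matrix, n_perm=n_perm, seed=seed,
                                     min_records=min_records)
    manova = niche_stats.pillai_manova(rec, rec["genus"])
    summary = niche_stats.genus_summary(rec)

    base_climate = world.climate[world.slices[0]]
    triple = hlz.climate_triple_rasters(base_climate["monthly_temp"],
                                        base_climate["precip"])
    maps = suitability.baseline_suitability(rec, triple)
    zone_matrix = suitability.genus_zone_means(maps, baseline)
    projections = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # novel-climate zones are expected late
        for sl in world.slices:
            projections[sl] = {
                g: suitability.project(zone_matrix, rasters[sl], g) for g in maps
            }

    result = PipelineResult(
        world=world, qc=qc_res, records=rec, grid=grid, hlz_rasters=rasters,
        dominant_hlz=dominant, indval=indval, manova=manova,
        genus_summary=summary, suitability_maps=maps, zone_matrix=zone_matrix,
        projections=projections,
    )
    if with_impact:
        _attach_impact(result, assignment, tau)
    return result


def _attach_impact(r: PipelineResult, assignment: pd.DataFrame, tau: float) -> None:
    world = r.world
    grid = r.grid
    hexes = grid.cells[["hex_id", "area_km2", "lon", "lat"]].copy()
    hexes["country"] = impact.assign_hex_countries(
        hexes.assign(
            geometry_lonlat=[grid.projection.inverse_geom(g)
                             for g in grid.cells["geometry"]]
        ),
        world.countries,
    )
    for stock, da in world.livestock.items():
        hexes[stock] = hexgrid.zonal_stats(da, grid, "sum",
                                           assignment=assignment).to_numpy()

    species_of = species_genus_map(world.clean_occurrences)
    host_of = dict(zip(world.clean_occurrences["species"],
                       world.clean_occurrences["host_class"]))

    tables = []
    for sl in world.slices:
        pop = hexgrid.zonal_stats(world.population[sl], grid, "sum",
                                  assignment=assignment)
        genus_suit = per_hex_genus_suitability(r.projections[sl], grid, assignment)
        human_tab = species_suitability_table(genus_suit, species_of, host_of,
                                              "human")
        hx = hexes.assign(population=pop.to_numpy())
        tables.append(impact.human_impact(hx, human_tab, world.biting_frequency, sl))
    r.impact_tables = pd.concat(tables, ignore_index=True)
    r.country_change = impact.country_aggregate(r.impact_tables,
                                                baseline_slice=world.slices[0])
    r.lat_profile = impact.latitudinal_profile(r.impact_tables, tau=tau)

    # livestock: baseline slice only (no future livestock surfaces exist)
    genus_suit0 = per_hex_genus_suitability(r.projections[world.slices[0]], grid,
                                            assignment)
    live_tab = species_suitability_table(genus_suit0, species_of, host_of,
                                         "livestock")
    # a hexagon is at risk when its best livestock-tick suitability reaches tau
    live_best = live_tab.groupby("hex_id")["suitability"].max()
    r.livestock_shares = impact.livestock_overlap(hexes, live_best, tau=tau)
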