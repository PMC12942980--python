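"""The synthetic world: determinism, construction contracts, and
Monte-Carlo consistency of the occurrence sampler."""

import numpy as np
import pandas as pd
import pytest
import shapely

from tickclim import grids, hlz, synthetic
from tickclim.synthetic import NicheSpec


# ------------------------------------------------------------ determinism
def test_identical_seeds_give_identical_worlds():
    a = synthetic.make_world(seed=3)
    b = synthetic.make_world(seed=3)
    pd.testing.assert_frame_equal(a.occurrences, b.occurrences)
    pd.testing.assert_frame_equal(a.truth, b.truth)
    for sl in a.slices:
        np.testing.assert_array_equal(
            a.climate[sl]["monthly_temp"].values, b.climate[sl]["monthly_temp"].values
        )
        np.testing.assert_array_equal(
            a.population[sl].values, b.population[sl].values
        )
    c = synthetic.make_world(seed=4)
    assert not a.occurrences.equals(c.occurrences)


# ---------------------------------------------------------------- climate
def test_zero_warming_means_identical_slices():
    clim = synthetic.gen_climate(warming_per_slice=0.0, seed=5)
    slices = sorted(clim)
    first = clim[slices[0]]["monthly_temp"].values
    for sl in slices[1:]:
        np.testing.assert_array_equal(clim[sl]["monthly_temp"].values, first)


def test_warming_is_exactly_additive():
    clim = synthetic.gen_climate(slices=(2020, 2040), warming_per_slice=2.0, seed=5)
    t0 = clim[2020]["monthly_temp"].values
    t1 = clim[2040]["monthly_temp"].values
    diff = t1 - t0
    np.testing.assert_allclose(diff[np.isfinite(diff)], 2.0, rtol=0, atol=1e-12)
    # precipitation untouched by warming
    np.testing.assert_array_equal(
        clim[2020]["precip"].values, clim[2040]["precip"].values
    )


def test_climate_structure_and_validation():
    clim = synthetic.gen_climate(seed=5)
    base = clim[2020]
    p = base["precip"].values
    assert np.all(p[np.isfinite(p)] > 0)
    # temperature falls toward the pole: compare low vs high latitude bands
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN ocean columns
        t = np.nanmean(base["monthly_temp"].values, axis=0)
    south = np.nanmean(t[:20])
    north = np.nanmean(t[-20:])
    assert south > north
    with pytest.raises(ValueError):
        synthetic.gen_climate(resolution=0.0)
    with pytest.raises(ValueError):
        synthetic.gen_climate(slices=())


# ------------------------------------------------------------ occurrences
def test_requested_record_counts_are_exact():
    clim = synthetic.gen_climate(seed=6)
    niche = NicheSpec("Solo", center=(10.0, 800.0, 0.74), spread=(2.0, 300.0, 0.3),
                      n_species=1, records_per_species=500)
    rec = synthetic.gen_occurrences([niche], clim[2020], seed=6)
    assert len(rec) == 500
    assert (rec["species"] == "Solo sp1").all()
    with pytest.raises(ValueError):
        synthetic.gen_occurrences([], clim[2020], seed=6)


def test_degenerate_effort_pins_all_records_to_one_cell():
    clim = synthetic.gen_climate(seed=6)
    base = clim[2020]
    eff = synthetic.gen_effort(base, seed=6)
    vals = np.zeros_like(eff.values)
    land = np.argwhere(np.isfinite(base["precip"].values))
    r, c = land[len(land) // 2]
    vals[r, c] = 1.0
    eff.values[:] = np.where(np.isfinite(eff.values), vals, np.nan)
    niche = NicheSpec("Solo", center=(10.0, 800.0, 0.74), spread=(5.0, 2000.0, 5.0),
                      n_species=1, records_per_species=50)
    rec = synthetic.gen_occurrences([niche], base, effort=eff, seed=6)
    lon = base["precip"]["lon"].values[c]
    lat = base["precip"]["lat"].values[r]
    assert np.all(np.abs(rec["lon"] - lon) <= 0.25)
    assert np.all(np.abs(rec["lat"] - lat) <= 0.25)


def test_sampler_matches_its_density_oracle():
    """Record means agree with the exact sampling-density expectation.

    The oracle is the normalized niche-density-times-effort distribution
    over land cells: its implied mean biotemperature per genus, with the
    Monte-Carlo standard error from the density variance.
    """
    clim = synthetic.gen_climate(seed=9)
    base = clim[2020]
    n = 500
    niches = [
        NicheSpec("Colda", center=(8.0, 900.0, 0.52), spread=(1.0, 2000.0, 5.0),
                  n_species=1, records_per_species=n),
        NicheSpec("Hotta", center=(18.0, 900.0, 1.18), spread=(1.0, 2000.0, 5.0),
                  n_species=1, records_per_species=n),
    ]
    rec = synthetic.gen_occurrences(niches, base, effort=None, seed=9)
    rec = hlz.extract_climate(rec, base["monthly_temp"], base["precip"])
    bt_r, pr_r, pet_r = hlz.climate_triple_rasters(base["monthly_temp"], base["precip"])
    land = np.isfinite(pr_r.values)
    bt, p, pet = (a.values[land] for a in (bt_r, pr_r, pet_r))
    for spec in niches:
        w = synthetic._niche_density(bt, p, pet, spec)
        prob = w / w.sum()
        mean = float(prob @ bt)
        se = float(np.sqrt(prob @ (bt - mean) ** 2 / n))
        got = rec.loc[rec["genus"] == spec.genus, "biotemperature"].mean()
        assert abs(got - mean) < 3 * se
        # the density mean itself sits close to the niche center
        assert abs(mean - spec.center[0]) < spec.spread[0]


def test_out_of_range_niche_center_warns():
    clim = synthetic.gen_climate(seed=6)
    bad = NicheSpec("Frosty", center=(-12.0, 800.0, 0.0001), spread=(1.0, 100.0, 0.1),
                    n_species=1, records_per_species=10)
    with pytest.warns(UserWarning, match="Frosty"):
        synthetic.gen_occurrences([bad], clim[2020], seed=6)


def test_niche_spec_validation():
    with pytest.raises(ValueError):
        NicheSpec("X", center=(5, 500, 0.5), spread=(0.0, 10, 0.1))
    with pytest.raises(ValueError):
        NicheSpec("X", center=(5, 500, 0.5), spread=(1, 10, 0.1), n_species=0)


# -------------------------------------------------------------- corruption
def test_zero_rates_leave_records_untouched(world):
    out, truth = synthetic.corrupt(world.clean_occurrences, 0.0, 0.0, 0.0, seed=1)
    assert len(truth) == 0
    pd.testing.assert_frame_equal(
        out.sort_values(["species", "lon", "lat"]).reset_index(drop=True),
        world.clean_occurrences.sort_values(["species", "lon", "lat"]).reset_index(drop=True),
    )


def test_injected_defect_counts_and_shapes(world):
    n = len(world.clean_occurrences)
    out, truth = synthetic.corrupt(world.clean_occurrences, 0.02, 0.03, 0.04, seed=1)
    counts = truth["defect"].value_counts()
    assert counts["duplicate"] == int(0.02 * n)
    assert counts["offshore"] == int(0.03 * n)
    assert counts["low_precision"] == int(0.04 * n)
    assert len(out) == n + counts["duplicate"]
    # every marked low-precision record has <= 2 written decimals
    low = out.loc[truth.loc[truth["defect"] == "low_precision", "row"]]
    for t in low["lon_text"]:
        assert len(t.split(".")[1]) <= 2
    # offshore rows fall outside the land polygon
    off = out.loc[truth.loc[truth["defect"] == "offshore", "row"]]
    assert not shapely.intersects(
        world.land, shapely.points(off["lon"].to_numpy(), off["lat"].to_numpy())
    ).any()


def test_corruption_rate_validation(world):
    with pytest.raises(ValueError, match="dup_rate"):
        synthetic.corrupt(world.clean_occurrences, dup_rate=1.5)


# ------------------------------------------- population, livestock, borders
def test_population_positive_and_growth():
    pop = synthetic.gen_population(slices=(2020, 2040), growth_per_slice=0.0, seed=2)
    np.testing.assert_array_equal(pop[2020].values, pop[2040].values)
    total = np.nansum(pop[2020].values)
    assert total > 0
    grown = synthetic.gen_population(slices=(2020, 2040), growth_per_slice=0.1, seed=2)
    assert np.nansum(grown[2040].values) == pytest.approx(1.1 * total)
    v = pop[2020].values
    assert np.all(v[np.isfinite(v)] >= 0)


def test_countries_partition_the_land():
    countries = synthetic.gen_countries(n_countries=5)
    land = synthetic.land_polygon()
    union = shapely.union_all(countries["geometry"].to_numpy())
    assert union.symmetric_difference(land).area < 1e-9
    for i in range(len(countries)):
        for j in range(i + 1, len(countries)):
            inter = countries["geometry"].iloc[i].intersection(countries["geometry"].iloc[j])
            assert inter.area < 1e-12  # strips touch only along borders
    with pytest.raises(ValueError):
        synthetic.gen_countries(n_countries=0)


def test_world_rasters_share_one_grid(world):
    base = world.climate[world.slices[0]]["precip"]
    for sl in world.slices:
        assert world.population[sl].shape == base.shape
    for da in world.livestock.values():
        assert da.shape == base.shape
    rec = world.clean_occurrences
    lon_min, lat_min, lon_max, lat_max = world.extent
    assert rec["lon"].between(lon_min, lon_max).all()
    assert rec["lat"].between(lat_min, lat_max).all()


def test_world_roundtrips_to_disk(world, tmp_path):
    synthetic.write_world(world, tmp_path)
    back = pd.read_csv(tmp_path / "occurrences.csv")
    assert len(back) == len(world.occurrences)
    import json

    gj = json.loads((tmp_path / "countries.geojson").read_text())
    assert len(gj["features"]) == len(world.countries)
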