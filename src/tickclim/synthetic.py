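"""Synthetic world generator: climate, niches, records, people, countries.

Everything downstream — cleaning, life-zone classification, indicator
tests, projection, exposure — is testable against this generator because
it carries its own ground truth.  The world is a small lon/lat window
with a latitudinally structured climate (warm wet equator-side, cold
pole-side, seasonality growing with latitude), a warming trend across
time slices, genus-specific Gaussian niches in (biotemperature,
precipitation, PET-ratio) space, spatially biased sampling effort,
record-level corruption (exact duplicates, offshore displacement,
coordinate-precision loss), log-normal human-population and livestock
surfaces, and latitudinal-strip countries partitioning the land.

One integer seed fans out to per-stage seeds by fixed offsets, so any
stage can be regenerated alone, bit-for-bit.

It makes no attempt to mimic real tick biogeography or the true sampling
effort of occurrence archives; it exists so the pipeline's arithmetic and
bookkeeping can be verified against known inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import xarray as xr
from scipy import ndimage

from . import grids, hlz
from .grids import Extent

# fixed per-stage seed offsets (stage reproducibility from one world seed)
_OFFSETS = {
    "climate": 11, "effort": 23, "occurrences": 37,
    "corrupt": 53, "population": 71, "livestock": 89,
}

DEFAULT_EXTENT: Extent = (-10.0, 0.0, 10.0, 70.0)
DEFAULT_RESOLUTION = 0.5
DEFAULT_SLICES = (2020, 2040, 2060, 2080, 2100)
#: degC added per 20-year slice; a high-end-scenario-like +4 degC by 2100
DEFAULT_WARMING_PER_SLICE = 1.0
#: land occupies the extent minus an ocean margin on the east/west edges
OCEAN_MARGIN_DEG = 1.5


@dataclass
class NicheSpec:
    """Gaussian climate niche of one genus and its sampling intensity."""

    genus: str
    center: tuple[float, float, float]   # biotemperature degC, precip mm, PET ratio
    spread: tuple[float, float, float]   # per-axis SD, same units
    n_species: int = 2
    records_per_species: int = 280

    def __post_init__(self):
        if any(s <= 0 for s in self.spread):
            raise ValueError("niche spreads must be strictly positive")
        if self.n_species < 1 or self.records_per_species < 1:
            raise ValueError("n_species and records_per_species must be >= 1")

    @property
    def species(self) -> list[str]:
        return [f"{self.genus} sp{k + 1}" for k in range(self.n_species)]


def default_niches() -> list[NicheSpec]:
    """Four genera spanning cold, temperate, hot-dry and hot-wet climates.

    Centers sit in the interior of a life-zone band (never on a band
    boundary) so each genus has a well-defined home zone; PET-ratio
    centers are consistent with the (biotemperature, precipitation)
    centers since the ratio is derived from them.
    """
    return [
        NicheSpec("Boreoixodes", center=(4.5, 700.0, 0.38), spread=(1.0, 120.0, 0.12)),
        NicheSpec("Nemoricola", center=(9.0, 750.0, 0.71), spread=(1.2, 120.0, 0.15)),
        NicheSpec("Xerocentor", center=(21.0, 350.0, 3.54), spread=(1.4, 60.0, 0.9)),
        NicheSpec("Tropidamma", center=(27.0, 2800.0, 0.57), spread=(1.4, 400.0, 0.12)),
    ]


def land_polygon(extent: Extent = DEFAULT_EXTENT,
                 margin: float = OCEAN_MARGIN_DEG) -> shapely.Polygon:
    """Land rectangle: the extent inset by the ocean margin on all sides."""
    lon_min, lat_min, lon_max, lat_max = extent
    return shapely.box(lon_min + margin, lat_min + margin / 3,
                       lon_max - margin, lat_max - margin / 3)


def gen_countries(extent: Extent = DEFAULT_EXTENT, n_countries: int = 7,
                  margin: float = OCEAN_MARGIN_DEG) -> pd.DataFrame:
    """Latitudinal-strip countries partitioning the land rectangle."""
    if n_countries < 1:
        raise ValueError("need at least one country")
    land = land_polygon(extent, margin)
    x0, y0, x1, y1 = shapely.bounds(land)
    edges = np.linspace(y0, y1, n_countries + 1)
    rows = [
        {"name": f"C{k + 1:02d}", "geometry": shapely.box(x0, edges[k], x1, edges[k + 1])}
        for k in range(n_countries)
    ]
    return pd.DataFrame(rows)


def _smooth_field(shape, rng, sigma_cells: float = 4.0) -> np.ndarray:
    """Unit-variance smooth Gaussian random field (spatial noise)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_cells, mode="nearest")
    return f / max(f.std(), 1e-12)


def gen_climate(extent: Extent = DEFAULT_EXTENT, resolution: float = DEFAULT_RESOLUTION,
                slices=DEFAULT_SLICES, warming_per_slice: float = DEFAULT_WARMING_PER_SLICE,
                seed: int = 0) -> dict[int, dict[str, xr.DataArray]]:
    """Monthly-temperature and annual-precipitation rasters per time slice.

    Baseline annual-mean temperature falls linearly with latitude plus a
    smooth random field; monthly values add a sinusoidal seasonal cycle
    whose amplitude grows with latitude; each successive slice adds
    ``warming_per_slice`` degC uniformly.  Precipitation is a strictly
    positive exponentiated smooth field, constant across slices.  Ocean
    cells are NaN.
    """
    if not len(slices):
        raise ValueError("need at least one time slice")
    lons, lats = grids.grid_coords(extent, resolution)
    rng = np.random.default_rng(seed + _OFFSETS["climate"])
    lon2, lat2 = np.meshgrid(lons, lats)

    t_mean = 29.0 - 0.5 * np.abs(lat2) + 1.2 * _smooth_field(lat2.shape, rng)
    amp = 2.0 + 0.18 * np.abs(lat2)
    month = np.arange(1, 13)
    seasonal = np.cos(2 * np.pi * (month[:, None, None] - 7) / 12.0)
    log_p = (
        np.log(900.0)
        + 0.8 * np.sin(2 * np.pi * lon2 / 20.0)
        - 0.004 * np.abs(lat2)
        + 0.5 * _smooth_field(lat2.shape, rng)
    )
    precip0 = np.exp(log_p)

    land = land_polygon(extent)
    inside = shapely.contains_xy(land, lon2.ravel(), lat2.ravel()).reshape(lat2.shape)
    ocean = ~inside

    out: dict[int, dict[str, xr.DataArray]] = {}
    for k, sl in enumerate(slices):
        t_monthly = t_mean[None, :, :] + amp[None, :, :] * seasonal + k * warming_per_slice
        t_monthly = np.where(ocean[None, :, :], np.nan, t_monthly)
        precip = np.where(ocean, np.nan, precip0)
        out[int(sl)] = {
            "monthly_temp": grids.monthly_raster(t_monthly, lons, lats, "monthly_temp"),
            "precip": grids.raster(precip, lons, lats, "precip"),
        }
    return out


def gen_effort(climate_slice: dict[str, xr.DataArray], seed: int = 0) -> xr.DataArray:
    """Spatially biased sampling-effort surface (smooth log-normal, mean ~1)."""
    precip = climate_slice["precip"]
    rng = np.random.default_rng(seed + _OFFSETS["effort"])
    f = np.exp(1.0 * _smooth_field(precip.shape, rng))
    f = np.where(np.isfinite(precip.values), f, np.nan)
    return grids.raster(f, precip["lon"].values, precip["lat"].values, "effort")


def _niche_density(bt, p, pet, spec: NicheSpec) -> np.ndarray:
    c, s = spec.center, spec.spread
    z = ((bt - c[0]) / s[0]) ** 2 + ((p - c[1]) / s[1]) ** 2 + ((pet - c[2]) / s[2]) ** 2
    return np.exp(-0.5 * z)


def gen_occurrences(niches: list[NicheSpec], climate_slice: dict[str, xr.DataArray],
                    effort: xr.DataArray | None = None, seed: int = 0,
                    host_classes=("human", "livestock")) -> pd.DataFrame:
    """Occurrence records sampled from each species' climate-niche density.

    Cells are drawn with probability proportional to the genus's Gaussian
    niche density at the cell's climate triple times the sampling effort;
    each record is jittered inside its cell and written with 4-decimal
    coordinate text.  Keys (species, lon/lat rounded to 3 decimals) are
    kept unique so the deduplication stage sees only injected duplicates.
    """
    import warnings

    if not niches:
        raise ValueError("need at least one niche")
    bt_r, pr_r, pet_r = hlz.climate_triple_rasters(
        climate_slice["monthly_temp"], climate_slice["precip"]
    )
    land = np.isfinite(pr_r.values)
    bt, p, pet = (a.values[land] for a in (bt_r, pr_r, pet_r))
    lon2, lat2 = np.meshgrid(pr_r["lon"].values, pr_r["lat"].values)
    cell_lon, cell_lat = lon2[land], lat2[land]
    eff = effort.values[land] if effort is not None else np.ones_like(bt)
    rlon, rlat = grids.resolution_of(pr_r)

    rng = np.random.default_rng(seed + _OFFSETS["occurrences"])
    rows = []
    used_keys: set[tuple[str, float, float]] = set()
    for spec in niches:
        if not (bt.min() - 1 <= spec.center[0] <= bt.max() + 1):
            warnings.warn(
                f"niche center of {spec.genus!r} outside attainable biotemperature "
                f"range [{bt.min():.1f}, {bt.max():.1f}]", stacklevel=2,
            )
        w = _niche_density(bt, p, pet, spec) * np.clip(eff, 0, None)
        if w.sum() <= 0:
            raise ValueError(f"no attainable climate for genus {spec.genus!r}")
        prob = w / w.sum()
        for sp_idx, species in enumerate(spec.species):
            host = host_classes[sp_idx % len(host_classes)]
            cells = rng.choice(prob.size, size=spec.records_per_species, p=prob)
            for c in cells:
                for _ in range(100):
                    lon = round(cell_lon[c] + rng.uniform(-0.49, 0.49) * rlon, 4)
                    lat = round(cell_lat[c] + rng.uniform(-0.49, 0.49) * rlat, 4)
                    key = (species, round(lon, 3), round(lat, 3))
                    if key not in used_keys:
                        used_keys.add(key)
                        break
                else:
                    raise RuntimeError("could not draw a unique record coordinate")
                rows.append({
                    "species": species, "genus": spec.genus,
                    "lon": lon, "lat": lat,
                    "lon_text": f"{lon:.4f}", "lat_text": f"{lat:.4f}",
                    "host_class": host, "qc_flag": "",
                })
    return pd.DataFrame(rows)


def corrupt(records: pd.DataFrame, dup_rate: float = 0.05, offshore_rate: float = 0.05,
            lowprec_rate: float = 0.05, seed: int = 0,
            extent: Extent = DEFAULT_EXTENT,
            margin: float = OCEAN_MARGIN_DEG) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inject duplicates, offshore displacements, and precision loss.

    The three defect sets are disjoint, so a QC run recovers exactly the
    injected counts.  Returns ``(corrupted, truth)`` where truth lists one
    row per injected defect (row index into the corrupted table, defect).
    """
    for name, r in (("dup_rate", dup_rate), ("offshore_rate", offshore_rate),
                    ("lowprec_rate", lowprec_rate)):
        if not 0 <= r <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {r}")
    n = len(records)
    rng = np.random.default_rng(seed + _OFFSETS["corrupt"])
    n_dup = int(np.floor(dup_rate * n))
    n_off = int(np.floor(offshore_rate * n))
    n_low = int(np.floor(lowprec_rate * n))
    picks = rng.choice(n, size=n_dup + n_off + n_low, replace=False)
    dup_idx = picks[:n_dup]
    off_idx = picks[n_dup:n_dup + n_off]
    low_idx = picks[n_dup + n_off:]

    out = records.reset_index(drop=True).copy()
    truth = []

    lon_min, _, lon_max, _ = extent
    # park offshore points in the east ocean margin, each on its own spot
    off_lons = np.round(np.linspace(lon_max - margin + 0.05, lon_max - 0.05, max(n_off, 1)), 4)
    for k, i in enumerate(off_idx):
        out.at[i, "lon"] = off_lons[k]
        out.at[i, "lon_text"] = f"{off_lons[k]:.4f}"
        truth.append({"row": int(i), "defect": "offshore"})

    for i in low_idx:
        lon = round(float(out.at[i, "lon"]), 2)
        lat = round(float(out.at[i, "lat"]), 2)
        out.at[i, "lon"] = lon
        out.at[i, "lat"] = lat
        out.at[i, "lon_text"] = f"{lon:.2f}"
        out.at[i, "lat_text"] = f"{lat:.2f}"
        truth.append({"row": int(i), "defect": "low_precision"})

    dup_rows = out.loc[dup_idx].copy()
    out = pd.concat([out, dup_rows], ignore_index=True)
    for k in range(n_dup):
        truth.append({"row": n + k, "defect": "duplicate"})

    out = out.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=False)
    # re-point truth rows at the shuffled positions
    pos = {old: new for new, old in enumerate(out["index"])}
    truth = [{"row": pos[t["row"]], "defect": t["defect"]} for t in truth]
    out = out.drop(columns="index")
    return out, pd.DataFrame(truth, columns=["row", "defect"])


def _lognormal_surface(extent, resolution, seed, scale_total, sigma=0.9):
    lons, lats = grids.grid_coords(extent, resolution)
    rng = np.random.default_rng(seed)
    lon2, lat2 = np.meshgrid(lons, lats)
    f = np.exp(sigma * _smooth_field(lat2.shape, rng) + 0.3 * sigma * rng.standard_normal(lat2.shape))
    land = land_polygon(extent)
    inside = shapely.contains_xy(land, lon2.ravel(), lat2.ravel()).reshape(lat2.shape)
    f = np.where(inside, f, np.nan)
    f = f * (scale_total / np.nansum(f))
    return grids.raster(f, lons, lats)


def gen_population(extent: Extent = DEFAULT_EXTENT, resolution: float = DEFAULT_RESOLUTION,
                   slices=DEFAULT_SLICES, growth_per_slice: float = 0.05,
                   total: float = 5e8, seed: int = 0) -> dict[int, xr.DataArray]:
    """Log-normal human-population rasters (persons/cell), growing per slice."""
    base = _lognormal_surface(extent, resolution, seed + _OFFSETS["population"], total)
    return {
        int(sl): (base * (1.0 + growth_per_slice) ** k).rename("population")
        for k, sl in enumerate(slices)
    }


def gen_livestock(extent: Extent = DEFAULT_EXTENT, resolution: float = DEFAULT_RESOLUTION,
                  totals={"cattle": 8e7, "sheep": 6e7, "goats": 5e7},
                  seed: int = 0) -> dict[str, xr.DataArray]:
    """Log-normal livestock rasters (head/cell) for cattle, sheep, goats."""
    return {
        stock: _lognormal_surface(
            extent, resolution, seed + _OFFSETS["livestock"] + j, tot
        ).rename(stock)
        for j, (stock, tot) in enumerate(totals.items())
    }


def biting_frequency_table(niches: list[NicheSpec]) -> pd.DataFrame:
    """Assign each species one of the five biting-frequency categories (cyclic)."""
    from .impact import FREQUENCY_CATEGORIES

    rows = []
    k = 0
    for spec in niches:
        for sp in spec.species:
            rows.append({"species": sp, "category": FREQUENCY_CATEGORIES[k % 5]})
            k += 1
    return pd.DataFrame(rows)


@dataclass
class SyntheticWorld:
    """A complete, internally registered synthetic study system."""

    seed: int
    extent: Extent
    resolution: float
    slices: tuple[int, ...]
    climate: dict[int, dict[str, xr.DataArray]]
    effort: xr.DataArray
    occurrences: pd.DataFrame            # corrupted table, as "observed"
    clean_occurrences: pd.DataFrame      # pre-corruption ground truth
    truth: pd.DataFrame                  # injected-defect labels
    niches: list[NicheSpec] = field(repr=False, default_factory=list)
    population: dict[int, xr.DataArray] = field(default_factory=dict)
    livestock: dict[str, xr.DataArray] = field(default_factory=dict)
    countries: pd.DataFrame | None = None
    land: shapely.Polygon | None = None
    biting_frequency: pd.DataFrame | None = None


def make_world(seed: int = 0, extent: Extent = DEFAULT_EXTENT,
               resolution: float = DEFAULT_RESOLUTION, slices=DEFAULT_SLICES,
               warming_per_slice: float = DEFAULT_WARMING_PER_SLICE,
               niches: list[NicheSpec] | None = None,
               dup_rate: float = 0.05, offshore_rate: float = 0.05,
               lowprec_rate: float = 0.05, n_countries: int = 7) -> SyntheticWorld:
    """Generate the full study system from one seed."""
    niches = default_niches() if niches is None else niches
    climate = gen_climate(extent, resolution, slices, warming_per_slice, seed)
    baseline = climate[int(slices[0])]
    effort = gen_effort(baseline, seed)
    clean = gen_occurrences(niches, baseline, effort, seed)
    corrupted, truth = corrupt(clean, dup_rate, offshore_rate, lowprec_rate, seed,
                               extent=extent)
    return SyntheticWorld(
        seed=seed, extent=extent, resolution=resolution, slices=tuple(int(s) for s in slices),
        climate=climate, effort=effort, occurrences=corrupted,
        clean_occurrences=clean, truth=truth, niches=niches,
        population=gen_population(extent, resolution, slices, seed=seed),
        livestock=gen_livestock(extent, resolution, seed=seed),
        countries=gen_countries(extent, n_countries),
        land=land_polygon(extent),
        biting_frequency=biting_frequency_table(niches),
    )


def write_world(world: SyntheticWorld, outdir) -> None:
    """Dump the world's tables and vectors as CSV / GeoJSON."""
    import json
    from pathlib import Path

    from shapely.geometry import mapping

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    world.occurrences.to_csv(outdir / "occurrences.csv", index=False)
    world.truth.to_csv(outdir / "truth_labels.csv", index=False)
    world.biting_frequency.to_csv(outdir / "biting_frequency.csv", index=False)
    features = [
        {"type": "Feature", "properties": {"name": r["name"]},
         "geometry": mapping(r["geometry"])}
        for _, r in world.countries.iterrows()
    ]
    (outdir / "countries.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
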