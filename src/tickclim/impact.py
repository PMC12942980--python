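"""Exposure-impact indices on the hexagonal grid.

Human impact per hexagon is modeled climate suitability multiplied by the
people living there, with each tick species weighted by how often it is
reported to bite humans.  The five-level biting-frequency scale (very
rare ... very frequent) maps onto numeric weights 0.8, 1.1, 1.4, 1.7, 2.0
(0.8 to 2.0 in increments of 0.3), so

    impact(h) = population(h) * sum_s w_s * p_s(h)

with p_s the suitability of species s in hexagon h (a species inherits
its genus's suitability map).  Because population(h) is hexagon area
times population density, the index is equivalently area-weighted
density, stated once here to avoid double-counting area.  Impacts are
additive over any partition of hexagons, which makes country and
latitude-band aggregation exact.  Persons (or stock) "at risk" are those
living in hexagons whose suitability meets a threshold tau (default 0.5,
the package's reading of "medium-to-high").
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely

FREQUENCY_CATEGORIES = (
    "very rare", "rare", "moderate", "frequent", "very frequent",
)
FREQUENCY_WEIGHTS = {c: 0.8 + 0.3 * k for k, c in enumerate(FREQUENCY_CATEGORIES)}

DEFAULT_TAU = 0.5


def frequency_weight(category: str) -> float:
    """Numeric biting-frequency weight for one of the five ordered labels."""
    try:
        return FREQUENCY_WEIGHTS[category]
    except KeyError:
        raise ValueError(
            f"unknown biting-frequency category {category!r}; "
            f"expected one of {FREQUENCY_CATEGORIES}"
        ) from None


def human_impact(hex_summary: pd.DataFrame, species_suitability: pd.DataFrame,
                 weights: pd.DataFrame, time_slice: int) -> pd.DataFrame:
    """Per-hexagon impact rows for one time slice.

    ``hex_summary`` needs hex_id, population (persons) and area_km2;
    ``species_suitability`` is tidy (hex_id, species, suitability);
    ``weights`` maps species -> category.  Raises if any species in the
    suitability table lacks a weight.
    """
    wmap = {
        s: frequency_weight(c)
        for s, c in zip(weights["species"], weights["category"])
    }
    missing = sorted(set(species_suitability["species"]) - set(wmap))
    if missing:
        raise ValueError(f"no biting-frequency weight for species: {missing}")
    ss = species_suitability.copy()
    ss["wp"] = ss["suitability"] * ss["species"].map(wmap)
    per_hex = ss.groupby("hex_id")["wp"].sum()
    mean_suit = ss.groupby("hex_id")["suitability"].mean()
    max_suit = ss.groupby("hex_id")["suitability"].max()

    out = hex_summary[["hex_id", "area_km2", "lon", "lat", "population"]].copy()
    if "country" in hex_summary.columns:
        out["country"] = hex_summary["country"]
    out["slice"] = time_slice
    out["weighted_suitability"] = out["hex_id"].map(per_hex).fillna(0.0)
    out["mean_suitability"] = out["hex_id"].map(mean_suit).fillna(0.0)
    out["max_suitability"] = out["hex_id"].map(max_suit).fillna(0.0)
    out["impact"] = out["population"] * out["weighted_suitability"]
    return out


def assign_hex_countries(grid_cells: pd.DataFrame, countries: pd.DataFrame) -> pd.Series:
    """One country per hexagon by largest-area intersection (keeps additivity)."""
    geoms = countries["geometry"].tolist()
    names = countries["name"].tolist()
    out = []
    for geom in grid_cells["geometry_lonlat"]:
        areas = [shapely.area(shapely.intersection(geom, g)) for g in geoms]
        out.append(names[int(np.argmax(areas))] if max(areas) > 0 else None)
    return pd.Series(out, index=grid_cells.index, name="country")


def country_aggregate(impact_tables: pd.DataFrame, baseline_slice: int) -> pd.DataFrame:
    """Per-country, per-slice totals and gain/loss areas relative to baseline.

    Gained area = total area of hexagons whose mean suitability rose since
    the baseline slice; lost analogously; net = gains - losses (km^2).
    """
    base = impact_tables[impact_tables["slice"] == baseline_slice]
    base_suit = base.set_index("hex_id")["mean_suitability"]
    rows = []
    for (country, sl), sub in impact_tables.groupby(["country", "slice"]):
        delta = sub["mean_suitability"].to_numpy() - sub["hex_id"].map(base_suit).to_numpy()
        gained = float(sub.loc[delta > 0, "area_km2"].sum())
        lost = float(sub.loc[delta < 0, "area_km2"].sum())
        rows.append({
            "country": country, "slice": sl,
            "impact": float(sub["impact"].sum()),
            "population": float(sub["population"].sum()),
            "gained_km2": gained, "lost_km2": lost,
            "net_km2": gained - lost,
        })
    return pd.DataFrame(rows)


def latitudinal_profile(impact_tables: pd.DataFrame, band_width: float = 10.0,
                        tau: float = DEFAULT_TAU,
                        suit_col: str = "max_suitability") -> pd.DataFrame:
    """Persons at risk per latitude band and slice.

    A hexagon's residents count as at risk when its suitability measure
    (by default the best — maximum — species suitability: the area is
    suitable for *some* tick) reaches tau; bands are [k*w, (k+1)*w)
    degrees, labeled by their lower edge.
    """
    t = impact_tables.copy()
    t["band"] = (np.floor(t["lat"] / band_width) * band_width).astype(float)
    t["at_risk"] = np.where(t[suit_col] >= tau, t["population"], 0.0)
    out = (
        t.groupby(["band", "slice"])
        .agg(persons_at_risk=("at_risk", "sum"), impact=("impact", "sum"))
        .reset_index()
    )
    return out


def livestock_overlap(hex_summary: pd.DataFrame, suitability: pd.Series,
                      stock_cols=("cattle", "sheep", "goats"),
                      tau: float = DEFAULT_TAU) -> pd.DataFrame:
    """Share of each stock kept in hexagons with suitability >= tau.

    Also reports the mean stock density (head/km^2) inside qualifying
    hexagons.  ``suitability`` is indexed by hex_id.
    """
    df = hex_summary.copy()
    df["suit"] = df["hex_id"].map(suitability).fillna(0.0)
    qual = df["suit"] >= tau
    rows = []
    for col in stock_cols:
        total = float(df[col].sum())
        inside = float(df.loc[qual, col].sum())
        area = float(df.loc[qual, "area_km2"].sum())
        rows.append({
            "stock": col,
            "share": inside / total if total > 0 else np.nan,
            "head_at_risk": inside,
            "density_in_risk_km2": inside / area if area > 0 else np.nan,
        })
    return pd.DataFrame(rows)
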