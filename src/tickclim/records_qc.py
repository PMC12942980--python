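"""Harmonization and quality control of tick occurrence records.

The cleaning chain mirrors standard practice for large georeferenced
compilations: harmonize heterogeneous source tables into one schema,
drop entries whose coordinates are written with fewer than three decimal
places, remove points falling offshore, remove records inconsistent with
a species' known country-level distribution, collapse repeated records,
and finally drop species left with fewer than ``min_records`` (default
200) accurate, georeferenced, non-duplicated records.

Precision is judged on the coordinate *as written* (text columns
``lon_text`` / ``lat_text`` when present), because a float cannot
distinguish "12.340" from "12.34".  Every filter returns the surviving
table plus the removed rows annotated with a ``qc_flag``; the record-local
filters (precision, offshore, checklist) commute, while the minimum-record
rule is order-dependent by design and always runs last.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

REQUIRED_COLUMNS = ("species", "lon", "lat")

FLAG_LOW_PRECISION = "low_precision"
FLAG_OFFSHORE = "offshore"
FLAG_CHECKLIST = "checklist_fail"
FLAG_DUPLICATE = "duplicate"
FLAG_MIN_RECORDS = "below_min_records"


def _decimals(text) -> int:
    """Number of decimal digits in a coordinate as written ("12.340" -> 3)."""
    s = str(text).strip().replace("−", "-")
    if "e" in s.lower():  # scientific notation: fall back to repr of the float
        s = repr(float(s))
    _, _, frac = s.partition(".")
    return len(frac)


def coordinate_decimals(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-record decimal counts for lon and lat, preferring text columns."""
    lon_src = records["lon_text"] if "lon_text" in records else records["lon"].map(repr)
    lat_src = records["lat_text"] if "lat_text" in records else records["lat"].map(repr)
    return lon_src.map(_decimals).to_numpy(), lat_src.map(_decimals).to_numpy()


def harmonize(raw: pd.DataFrame, mapping: dict[str, str] | None = None):
    """Map a raw table onto the unified record schema.

    ``mapping`` sends unified names (species, lon, lat, optionally
    host_class, country, source, lon_text, lat_text) to raw column names;
    identity for columns already well-named.  Genus is derived from the
    species binomial.  Rows with unparseable or out-of-range coordinates
    are dropped and counted.

    Returns ``(records, n_dropped)``.
    """
    mapping = mapping or {}
    df = raw.rename(columns={v: k for k, v in mapping.items()}).copy()
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col!r}")
    if "lon_text" not in df.columns:
        df["lon_text"] = df["lon"].astype(str)
    if "lat_text" not in df.columns:
        df["lat_text"] = df["lat"].astype(str)
    for c in ("lon", "lat"):
        df[c] = pd.to_numeric(
            df[c].astype(str).str.replace("−", "-", regex=False), errors="coerce"
        )
    ok = (
        df["lon"].notna() & df["lat"].notna()
        & df["lon"].between(-180, 180) & df["lat"].between(-90, 90)
    )
    dropped = int((~ok).sum())
    df = df.loc[ok].copy()
    df["genus"] = df["species"].astype(str).str.strip().str.split().str[0]
    if "host_class" not in df.columns:
        df["host_class"] = "other"
    if "qc_flag" not in df.columns:
        df["qc_flag"] = ""
    return df.reset_index(drop=True), dropped


def _split(records: pd.DataFrame, keep: np.ndarray, flag: str):
    removed = records.loc[~keep].copy()
    removed["qc_flag"] = flag
    return records.loc[keep].copy(), removed


def filter_precision(records: pd.DataFrame, min_decimals: int = 3):
    """Keep records whose coordinates both carry >= min_decimals decimals."""
    dlon, dlat = coordinate_decimals(records)
    keep = (dlon >= min_decimals) & (dlat >= min_decimals)
    return _split(records, keep, FLAG_LOW_PRECISION)


def filter_offshore(records: pd.DataFrame, land):
    """Keep records whose point intersects land (boundary points kept).

    ``land`` is any shapely geometry (polygon / multipolygon) in lon/lat.
    """
    pts = shapely.points(records["lon"].to_numpy(), records["lat"].to_numpy())
    keep = shapely.intersects(land, pts)
    return _split(records, keep, FLAG_OFFSHORE)


def assign_countries(records: pd.DataFrame, countries: pd.DataFrame) -> pd.Series:
    """Containing-country name per record (NaN when none contains the point).

    ``countries`` has columns ``name`` and ``geometry`` (shapely, lon/lat).
    """
    tree = STRtree(countries["geometry"].tolist())
    pts = shapely.points(records["lon"].to_numpy(), records["lat"].to_numpy())
    out = np.full(len(records), None, dtype=object)
    idx_pt, idx_poly = tree.query(pts, predicate="intersects")
    # first match wins; polygons are expected to be interior-disjoint
    for p, c in zip(idx_pt[::-1], idx_poly[::-1]):
        out[p] = countries["name"].iloc[c]
    return pd.Series(out, index=records.index, name="country")


def filter_checklist(records: pd.DataFrame, checklist: dict[str, set],
                     countries: pd.DataFrame | None = None):
    """Keep records whose country is in the species' known set.

    Species absent from the checklist are retained and flagged (their
    distribution is simply unknown).  Country assignment is spatial when
    country polygons are supplied, else the record's ``country`` field.
    """
    if countries is not None:
        country = assign_countries(records, countries)
    elif "country" in records.columns:
        country = records["country"]
    else:
        raise ValueError("filter_checklist needs country polygons or a country column")
    known = records["species"].map(lambda s: s in checklist)
    allowed = [
        (c in checklist.get(s, ())) if k else True
        for s, c, k in zip(records["species"], country, known)
    ]
    kept, removed = _split(records, np.asarray(allowed), FLAG_CHECKLIST)
    unknown = ~known.loc[kept.index]
    kept.loc[unknown, "qc_flag"] = kept.loc[unknown, "qc_flag"].where(
        kept.loc[unknown, "qc_flag"] != "", "checklist_missing"
    )
    return kept, removed


def deduplicate(records: pd.DataFrame, min_decimals: int = 3):
    """Collapse repeated records on the (species, rounded lon, rounded lat) key.

    Coordinates are rounded at ``min_decimals`` so harmonization noise in
    later digits does not defeat the key; the first record per key survives.
    """
    key = pd.MultiIndex.from_arrays([
        records["species"],
        records["lon"].round(min_decimals),
        records["lat"].round(min_decimals),
    ])
    keep = ~key.duplicated(keep="first")
    return _split(records, np.asarray(keep), FLAG_DUPLICATE)


def filter_min_records(records: pd.DataFrame, threshold: int = 200):
    """Keep species with at least ``threshold`` surviving records."""
    counts = records.groupby("species")["species"].transform("size")
    return _split(records, (counts >= threshold).to_numpy(), FLAG_MIN_RECORDS)


def qc_report(steps: list[tuple[str, int]], n_in: int, n_out: int) -> pd.DataFrame:
    """Per-filter removal counts; total removals must equal n_in - n_out."""
    report = pd.DataFrame(steps, columns=["filter", "removed"])
    if int(report["removed"].sum()) != n_in - n_out:
        raise AssertionError("QC accounting violated: removals != rows lost")
    return report


@dataclass
class QCResult:
    clean: pd.DataFrame
    report: pd.DataFrame
    removed: pd.DataFrame


def run_qc(records: pd.DataFrame, land=None, checklist=None,
           countries: pd.DataFrame | None = None, min_decimals: int = 3,
           min_records: int = 200) -> QCResult:
    """Full cleaning chain; stages with missing inputs are skipped with count 0."""
    n_in = len(records)
    steps: list[tuple[str, int]] = []
    removed_parts = []
    df = records

    df, rem = filter_precision(df, min_decimals)
    steps.append((FLAG_LOW_PRECISION, len(rem)))
    removed_parts.append(rem)
    if land is not None:
        df, rem = filter_offshore(df, land)
        steps.append((FLAG_OFFSHORE, len(rem)))
        removed_parts.append(rem)
    if checklist is not None:
        df, rem = filter_checklist(df, checklist, countries)
        steps.append((FLAG_CHECKLIST, len(rem)))
        removed_parts.append(rem)
    df, rem = deduplicate(df, min_decimals)
    steps.append((FLAG_DUPLICATE, len(rem)))
    removed_parts.append(rem)
    df, rem = filter_min_records(df, min_records)
    steps.append((FLAG_MIN_RECORDS, len(rem)))
    removed_parts.append(rem)

    removed = pd.concat(removed_parts) if removed_parts else records.iloc[:0]
    return QCResult(
        clean=df.reset_index(drop=True),
        report=qc_report(steps, n_in, len(df)),
        removed=removed.reset_index(drop=True),
    )
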