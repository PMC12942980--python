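"""Genus-level climate niches, indicator species analysis, and MANOVA.

The indicator value (IndVal) of species *i* for zone *j* is

    IndVal_ij = A_ij * B_ij * 100

where specificity ``A_ij`` is the share of the species' records collected
in zone *j* and fidelity ``B_ij`` is the share of zone-*j* sites occupied
by the species.  ``stat = sqrt(A*B)`` is the same quantity on the [0, 1]
square-root scale on which indicator statistics are conventionally
reported.  Significance of a species' best zone comes from permuting the
site -> zone labeling: p = (r + 1) / (n_perm + 1), with r the number of
permutations whose best-zone statistic reaches the observed one.

The one-way MANOVA asks whether genera differ in their joint
(biotemperature, precipitation, PET-ratio) distribution; Pillai's trace
V = tr(H (H+E)^-1) with its standard F approximation is computed from
the between/within cross-product matrices directly (robust at the exact
null, where generic eigenvalue routes degenerate); a singularity
pre-check names any collinear response first.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

CLIMATE_AXES = ("biotemperature", "precipitation", "pet_ratio")


@dataclass
class SiteSpeciesMatrix:
    """Site x species record counts plus the one HLZ label per site."""

    counts: pd.DataFrame       # index: site id, columns: species
    zones: pd.Series           # index: site id -> HLZ id

    def __post_init__(self):
        if not self.counts.index.equals(self.zones.index):
            raise ValueError("counts and zones must share the same site index")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("record counts must be non-negative")

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    @property
    def species(self):
        return list(self.counts.columns)


def build_matrix(records: pd.DataFrame, site_col: str = "hex_id",
                 zone_col: str = "hlz", species_col: str = "species",
                 site_zones: pd.Series | None = None) -> SiteSpeciesMatrix:
    """Cross-tabulate annotated records into a site x species matrix.

    Each occupied site gets one HLZ label: ``site_zones`` when given
    (e.g. the dominant class of a hexagon), else the modal ``zone_col``
    among the site's records.
    """
    counts = pd.crosstab(records[site_col], records[species_col])
    counts.index.name = "site"
    record_mode = (
        records.groupby(site_col)[zone_col]
        .agg(lambda z: z.value_counts().sort_index().idxmax())
        .reindex(counts.index)
        if zone_col in records.columns else None
    )
    if site_zones is not None:
        zones = site_zones.reindex(counts.index)
        if zones.isna().any():
            # tiny coastal sites can miss a raster-derived label; fall back
            # to the modal zone of the site's own records
            if record_mode is None:
                raise ValueError("site_zones missing labels for some occupied sites")
            zones = zones.fillna(record_mode)
    else:
        zones = record_mode
    if zones is None or zones.isna().any():
        raise ValueError("could not label every occupied site with a zone")
    return SiteSpeciesMatrix(counts=counts, zones=zones.astype(np.int64))


def specificity(matrix: SiteSpeciesMatrix, species: str, zone: int) -> float:
    """A: share of the species' records collected in the zone."""
    col = matrix.counts[species]
    total = col.sum()
    if total == 0:
        raise ValueError(f"species {species!r} has no records")
    return float(col[matrix.zones == zone].sum() / total)


def fidelity(matrix: SiteSpeciesMatrix, species: str, zone: int) -> float:
    """B: share of the zone's sites in which the species occurs."""
    in_zone = matrix.zones == zone
    n_sites = int(in_zone.sum())
    if n_sites == 0:
        raise ValueError(f"zone {zone} has no sites")
    return float((matrix.counts.loc[in_zone, species] > 0).sum() / n_sites)


def _best_zone_stats(counts: np.ndarray, presence: np.ndarray, zones: np.ndarray,
                     zone_ids: np.ndarray):
    """Per-species best zone and best stat for one site->zone labeling.

    counts/presence: (sites, species); returns (best_zone_idx, best_stat)
    with ties broken toward the lower zone id (zone_ids sorted ascending).
    """
    onehot = zones[:, None] == zone_ids[None, :]          # sites x zones
    rec_in_zone = counts.T @ onehot                        # species x zones
    totals = counts.sum(axis=0)[:, None]
    A = np.divide(rec_in_zone, totals, out=np.zeros_like(rec_in_zone, dtype=float),
                  where=totals > 0)
    sites_per_zone = onehot.sum(axis=0)[None, :]
    occ_in_zone = presence.T.astype(float) @ onehot
    B = np.divide(occ_in_zone, sites_per_zone,
                  out=np.zeros_like(occ_in_zone), where=sites_per_zone > 0)
    stat = np.sqrt(A * B)
    best = stat.argmax(axis=1)                             # first max -> lowest id
    return best, stat[np.arange(stat.shape[0]), best], A, B


def indval_test(matrix: SiteSpeciesMatrix, n_perm: int | str = 999,
                seed: int | None = None, min_records: int = 200) -> pd.DataFrame:
    """Indicator-species test: best zone per species with permutation p-value.

    Species with ``<= min_records`` total records are excluded (strictly
    more than ``min_records`` required).  ``n_perm="exact"`` enumerates
    every ordering of the site labels — only sensible for tiny matrices.

    Returns a table with columns species, zone, A, B, indval, stat, p_value.
    """
    zone_ids = np.sort(matrix.zones.unique())
    if zone_ids.size < 2:
        raise ValueError("indicator analysis needs at least two zones")
    if n_perm != "exact" and int(n_perm) < 1:
        raise ValueError("n_perm must be >= 1")

    totals = matrix.counts.sum(axis=0)
    species = [s for s in matrix.species if totals[s] > min_records]
    if not species:
        return pd.DataFrame(columns=["species", "zone", "A", "B", "indval", "stat", "p_value"])
    counts = matrix.counts[species].to_numpy(dtype=float)
    presence = counts > 0
    zones = matrix.zones.to_numpy()

    best, obs_stat, A, B = _best_zone_stats(counts, presence, zones, zone_ids)

    if n_perm == "exact":
        perms = [np.asarray(p) for p in itertools.permutations(range(zones.size))]
        perm_iter = (zones[p] for p in perms)
        n_total = len(perms)
    else:
        rng = np.random.default_rng(seed)
        n_total = int(n_perm)
        perm_iter = (rng.permutation(zones) for _ in range(n_total))

    exceed = np.zeros(len(species), dtype=np.int64)
    for z in perm_iter:
        _, s, _, _ = _best_zone_stats(counts, presence, z, zone_ids)
        exceed += s >= obs_stat - 1e-12
    p = (exceed + 1) / (n_total + 1)

    rows = []
    for k, sp in enumerate(species):
        z = int(zone_ids[best[k]])
        a, b = float(A[k, best[k]]), float(B[k, best[k]])
        rows.append({
            "species": sp, "zone": z, "A": a, "B": b,
            "indval": a * b * 100.0, "stat": float(obs_stat[k]),
            "p_value": float(min(p[k], 1.0)),
        })
    return pd.DataFrame(rows)


@dataclass
class ManovaResult:
    pillai: float
    F: float
    df_hypothesis: int    # groups - 1
    df_num: float         # numerator df of the Pillai F approximation
    df_den: float
    p_value: float
    n_groups: int
    n_obs: int


def pillai_manova(climate: pd.DataFrame, labels: pd.Series | np.ndarray,
                  exclude: list[str] | None = None,
                  axes=CLIMATE_AXES) -> ManovaResult:
    """One-way MANOVA of the climate triple on group (genus) labels.

    Groups in ``exclude`` (e.g. genera with too few records to define a
    niche) are removed first.  Raises on a singular within-group problem,
    naming the offending response.
    """
    labels = pd.Series(np.asarray(labels), name="group")
    X = climate.loc[:, list(axes)].reset_index(drop=True)
    mask = ~labels.isin(exclude or [])
    X, labels = X.loc[mask.to_numpy()], labels[mask]
    groups = labels.unique()
    if len(groups) < 2:
        raise ValueError("MANOVA needs at least two groups after exclusion")

    # within-group cross-products; singular => some response is collinear
    Xc = X.to_numpy(dtype=float)
    E = np.zeros((Xc.shape[1], Xc.shape[1]))
    for g in groups:
        sub = Xc[(labels == g).to_numpy()]
        d = sub - sub.mean(axis=0)
        E += d.T @ d
    diag = np.sqrt(np.diag(E))
    if np.any(diag == 0):
        bad = list(np.asarray(axes)[diag == 0])
        raise ValueError(f"singular within-group matrix: constant response {bad}")
    corr = E / np.outer(diag, diag)
    if np.linalg.matrix_rank(corr, tol=1e-10) < corr.shape[0]:
        # point at the response most collinear with the rest
        r2 = [
            1 - 1 / np.linalg.inv(corr + 1e-12 * np.eye(len(axes)))[j, j]
            for j in range(len(axes))
        ]
        raise ValueError(
            f"singular within-group matrix: collinear response {axes[int(np.argmax(r2))]!r}"
        )

    # between-group cross-products and Pillai V = tr(H (H+E)^-1),
    # with the standard F approximation
    grand = Xc.mean(axis=0)
    H = np.zeros_like(E)
    for g in groups:
        sub = Xc[(labels == g).to_numpy()]
        d = (sub.mean(axis=0) - grand)[:, None]
        H += len(sub) * (d @ d.T)
    V = float(np.trace(np.linalg.solve((H + E).T, H.T).T))

    N, p = Xc.shape
    q = len(groups) - 1
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    n_half = (N - len(groups) - p - 1) / 2.0
    df_num = s * (2 * m + s + 1)
    df_den = s * (2 * n_half + s + 1)
    ratio = V / s
    if ratio >= 1.0:
        F, p_value = np.inf, 0.0
    else:
        F = (df_den / df_num) * ratio / (1.0 - ratio)
        from scipy import stats as sps

        p_value = float(sps.f.sf(F, df_num, df_den))
    return ManovaResult(
        pillai=V,
        F=float(F),
        df_hypothesis=q,
        df_num=float(df_num),
        df_den=float(df_den),
        p_value=p_value,
        n_groups=len(groups),
        n_obs=N,
    )


def genus_summary(records: pd.DataFrame, axes=CLIMATE_AXES,
                  group_col: str = "genus") -> pd.DataFrame:
    """Per-genus five-number summary (min/q25/median/q75/max) per climate axis."""
    q = records.groupby(group_col)[list(axes)].quantile([0.0, 0.25, 0.5, 0.75, 1.0])
    q = q.unstack(level=-1)
    q.columns = [f"{axis}_{name}" for axis, quant in q.columns.to_flat_index()
                 for name in [{0.0: "min", 0.25: "q25", 0.5: "median",
                               0.75: "q75", 1.0: "max"}[quant]]]
    n = records.groupby(group_col).size().rename("n_records")
    return q.join(n)
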