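"""Indicator-species statistics against brute-force enumeration, and the
MANOVA against its closed-form two-group equivalence."""

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from tickclim import hlz, niche_stats as ns


def toy_matrix(counts, zones, species=None):
    species = species or [f"sp{j}" for j in range(np.shape(counts)[1])]
    counts = pd.DataFrame(np.asarray(counts), columns=species)
    counts.index.name = "site"
    return ns.SiteSpeciesMatrix(
        counts=counts, zones=pd.Series(zones, index=counts.index)
    )


# ------------------------------------------------------------ the matrix
def test_build_matrix_counts_and_presence():
    rec = pd.DataFrame({
        "hex_id": [1, 1, 2],
        "species": ["A a", "A a", "B b"],
        "hlz": [5, 5, 9],
    })
    mat = ns.build_matrix(rec)
    assert mat.counts.loc[1, "A a"] == 2
    assert bool(mat.presence.loc[1, "A a"])
    assert mat.counts.to_numpy().sum() == len(rec)
    assert mat.zones.to_dict() == {1: 5, 2: 9}


# --------------------------------------------------- specificity/fidelity
def test_specificity_and_fidelity_arithmetic():
    # species 0: 30 of 120 records in zone 1; present in 3 of 12 zone-1 sites
    counts = np.zeros((16, 1), dtype=int)
    counts[:3, 0] = 10          # 30 records spread over 3 zone-1 sites
    counts[12:15, 0] = 30       # 90 records in zone-2 sites
    zones = [1] * 12 + [2] * 4
    mat = toy_matrix(counts, zones)
    assert ns.specificity(mat, "sp0", 1) == pytest.approx(0.25)
    assert ns.fidelity(mat, "sp0", 1) == pytest.approx(0.25)
    assert ns.specificity(mat, "sp0", 2) == pytest.approx(0.75)
    with pytest.raises(ValueError):
        ns.fidelity(mat, "sp0", 99)


def test_perfect_indicator_is_maximal():
    # all records in zone 1, present in every zone-1 site
    mat = toy_matrix([[4, 0], [2, 0], [0, 3], [0, 3]], [1, 1, 2, 2])
    res = ns.indval_test(mat, n_perm=99, seed=0, min_records=0)
    row = res.set_index("species").loc["sp0"]
    assert row["zone"] == 1
    assert row["A"] == 1.0 and row["B"] == 1.0
    assert row["indval"] == 100.0 and row["stat"] == 1.0


def test_even_spread_over_two_zones_gives_half():
    # equal records in two equal-size zones, present in every site
    mat = toy_matrix([[5], [5], [5], [5]], [1, 1, 2, 2])
    res = ns.indval_test(mat, n_perm=9, seed=0, min_records=0)
    row = res.iloc[0]
    assert row["A"] == pytest.approx(0.5) and row["B"] == 1.0
    assert row["indval"] == pytest.approx(50.0)
    assert row["zone"] == 1  # tie broken toward the lower zone id


# -------------------------------------------- exact permutation p-values
def brute_force_p(counts, zones):
    """Exhaustive-enumeration IndVal p-values with exact rational arithmetic."""
    counts = np.asarray(counts)
    n_sites, n_species = counts.shape
    zones = list(zones)
    zone_ids = sorted(set(zones))

    def best_stat_sq(z):
        out = []
        for s in range(n_species):
            total = counts[:, s].sum()
            best = Fraction(0)
            for zid in zone_ids:
                sites = [i for i in range(n_sites) if z[i] == zid]
                a = Fraction(int(counts[sites, s].sum()), int(total))
                b = Fraction(sum(counts[i, s] > 0 for i in sites), len(sites))
                best = max(best, a * b)
            out.append(best)
        return out

    obs = best_stat_sq(zones)
    perms = [list(p) for p in itertools.permutations(zones)]
    exceed = [sum(best_stat_sq(z)[s] >= obs[s] for z in perms) for s in range(n_species)]
    return [(e + 1) / (len(perms) + 1) for e in exceed]


@pytest.mark.parametrize("counts, zones", [
    ([[3, 1], [1, 0], [0, 4]], [1, 1, 2]),
    ([[2, 0], [0, 1], [1, 3]], [1, 2, 3]),
    ([[5, 1], [0, 2], [3, 0], [0, 4]], [1, 1, 2, 2]),
])
def test_exact_permutation_matches_enumeration(counts, zones):
    mat = toy_matrix(counts, zones)
    res = ns.indval_test(mat, n_perm="exact", min_records=0)
    want = brute_force_p(counts, zones)
    for s, p in enumerate(want):
        assert res["p_value"].iloc[s] == pytest.approx(float(p), abs=1e-12)


def test_indval_needs_two_zones_and_respects_min_records():
    with pytest.raises(ValueError, match="two zones"):
        ns.indval_test(toy_matrix([[1], [2]], [1, 1]), n_perm=9)
    # species totals 210 and 300: the record threshold is strict (> min)
    mat = toy_matrix([[150, 300], [60, 0]], [1, 2])
    assert len(ns.indval_test(mat, n_perm=9, seed=0, min_records=200)) == 2
    res = ns.indval_test(mat, n_perm=9, seed=0, min_records=210)
    assert list(res["species"]) == ["sp1"]


def test_permutation_p_reproducible_with_seed():
    mat = toy_matrix([[3, 1], [1, 0], [0, 4], [2, 2]], [1, 1, 2, 2])
    a = ns.indval_test(mat, n_perm=199, seed=5, min_records=0)
    b = ns.indval_test(mat, n_perm=199, seed=5, min_records=0)
    pd.testing.assert_frame_equal(a, b)
    assert ((a["p_value"] > 0) & (a["p_value"] <= 1)).all()


# ----------------------------------------------------------------- MANOVA
def _hand_pillai(X, labels):
    """Independent eigenvalue-route Pillai trace."""
    X = np.asarray(X, dtype=float)
    groups = pd.unique(labels)
    grand = X.mean(axis=0)
    H = np.zeros((X.shape[1], X.shape[1]))
    E = np.zeros_like(H)
    for g in groups:
        sub = X[np.asarray(labels) == g]
        d = (sub.mean(axis=0) - grand)[:, None]
        H += len(sub) * (d @ d.T)
        c = sub - sub.mean(axis=0)
        E += c.T @ c
    eig = np.linalg.eigvals(np.linalg.solve(E + H, H))
    return float(np.sum(eig.real))


def _random_climate(rng, n, shift):
    bt = rng.uniform(5, 25, n) + shift
    p = np.exp(rng.uniform(np.log(300), np.log(3000), n))
    return pd.DataFrame({
        "biotemperature": bt, "precipitation": p,
        "pet_ratio": hlz.PET_PER_DEGREE * bt / p,
    })


def test_two_group_pillai_equals_hotelling_closed_form(rng):
    X = pd.concat([_random_climate(rng, 40, 0.0), _random_climate(rng, 35, 3.0)],
                  ignore_index=True)
    labels = np.array(["a"] * 40 + ["b"] * 35)
    res = ns.pillai_manova(X, labels)
    # Hotelling two-sample T^2 computed independently
    xa = X.iloc[:40].to_numpy()
    xb = X.iloc[40:].to_numpy()
    n1, n2 = len(xa), len(xb)
    d = xa.mean(axis=0) - xb.mean(axis=0)
    S = ((n1 - 1) * np.cov(xa.T) + (n2 - 1) * np.cov(xb.T)) / (n1 + n2 - 2)
    T2 = (n1 * n2 / (n1 + n2)) * d @ np.linalg.solve(S, d)
    assert res.pillai == pytest.approx(T2 / (T2 + n1 + n2 - 2), abs=1e-10)


def test_identical_group_means_give_null_trace(rng):
    block = _random_climate(rng, 30, 0.0)
    X = pd.concat([block, block], ignore_index=True)
    labels = np.array(["a"] * 30 + ["b"] * 30)
    res = ns.pillai_manova(X, labels)
    assert abs(res.pillai) < 1e-10


def test_hypothesis_df_counts_groups(rng):
    parts = [_random_climate(rng, 12, k * 0.7) for k in range(10)]
    X = pd.concat(parts, ignore_index=True)
    labels = np.repeat([f"g{k}" for k in range(10)], 12)
    res = ns.pillai_manova(X, labels)
    assert res.df_hypothesis == 9
    assert res.pillai == pytest.approx(
        _hand_pillai(X.to_numpy(), labels), abs=1e-8
    )


def test_pillai_matches_statsmodels(rng):
    """Cross-check trace, F and dfs against an independent implementation."""
    from statsmodels.multivariate.manova import MANOVA

    X = pd.concat([_random_climate(rng, 25, k * 1.5) for k in range(3)],
                  ignore_index=True)
    labels = np.repeat(["a", "b", "c"], 25)
    res = ns.pillai_manova(X, labels)
    data = X.copy()
    data.columns = ["y0", "y1", "y2"]
    data["g"] = labels
    tab = MANOVA.from_formula("y0 + y1 + y2 ~ C(g)", data=data).mv_test()
    row = tab.results["C(g)"]["stat"].loc["Pillai's trace"]
    assert res.pillai == pytest.approx(float(row["Value"]), abs=1e-10)
    assert res.F == pytest.approx(float(row["F Value"]), rel=1e-8)
    assert (res.df_num, res.df_den) == (float(row["Num DF"]), float(row["Den DF"]))
    assert res.p_value == pytest.approx(float(row["Pr > F"]), abs=1e-12)


def test_exclusion_and_singularity_error(rng):
    X = pd.concat([_random_climate(rng, 20, 0.0), _random_climate(rng, 20, 2.0),
                   _random_climate(rng, 3, 9.0)], ignore_index=True)
    labels = np.array(["a"] * 20 + ["b"] * 20 + ["junk"] * 3)
    res = ns.pillai_manova(X, labels, exclude=["junk"])
    assert res.n_groups == 2
    bad = X.copy()
    bad["pet_ratio"] = 2.0 * bad["biotemperature"]  # exactly collinear
    with pytest.raises(ValueError, match="pet_ratio|biotemperature"):
        ns.pillai_manova(bad, labels)


# ---------------------------------------------------------- genus summary
def test_genus_summary_quantiles(clean_annotated):
    single = clean_annotated.head(1)
    s = ns.genus_summary(single)
    v = single["biotemperature"].iloc[0]
    assert s["biotemperature_min"].iloc[0] == s["biotemperature_max"].iloc[0] == v
    full = ns.genus_summary(clean_annotated)
    for ax in ns.CLIMATE_AXES:
        cols = [f"{ax}_{q}" for q in ("min", "q25", "median", "q75", "max")]
        vals = full[cols].to_numpy()
        assert (np.diff(vals, axis=1) >= 0).all()
    assert full["n_records"].sum() == len(clean_annotated)
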