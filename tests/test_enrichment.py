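"""Hypergeometric enrichment: sliding windows, modules, hexamers."""

import math

import numpy as np
import pandas as pd
import pytest

from splicestage.datamodel import ExonCatalog, GeneSetCollection
from splicestage.enrichment import (
    cluster_enrichment_profiles,
    hexamer_enrichment,
    hypergeom_upper,
    module_enrichment,
    n_windows,
    sliding_window_enrichment,
)
from splicestage.synthetic import simulate_sequences


def hypergeom_upper_oracle(k, K, n, N):
    """P(X >= k) by direct summation of counting ratios."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return min(total, 1.0)


def catalog_of(genes_per_exon):
    rows = []
    for exon, gene in genes_per_exon.items():
        rows.append({"gene_id": gene, "chrom": "chr1", "start": 0, "end": 1,
                     "strand": "+", "novelty": "known"})
    return ExonCatalog(pd.DataFrame(rows, index=list(genes_per_exon)))


# ------------------------------------------------------- hypergeom_upper

def test_hypergeom_hand_value_and_boundaries():
    assert hypergeom_upper(4, 5, 4, 10) == pytest.approx(5 / 210)
    assert hypergeom_upper(0, 5, 4, 10) == 1.0
    with pytest.raises(ValueError):
        hypergeom_upper(6, 5, 4, 10)


def test_hypergeom_matches_enumeration_for_small_populations():
    for N in range(1, 16):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    assert hypergeom_upper(k, K, n, N) == pytest.approx(
                        hypergeom_upper_oracle(k, K, n, N), rel=1e-9, abs=1e-12
                    )


def test_tail_monotone_in_k():
    ps = [hypergeom_upper(k, 10, 8, 30) for k in range(9)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


# ------------------------------------------------------- window geometry

def test_window_count_formula():
    assert n_windows(964, 300, 1) == 665
    assert n_windows(300, 300, 1) == 1
    assert n_windows(10, 3, 2) == 4
    with pytest.raises(ValueError):
        n_windows(100, 300)


@pytest.mark.parametrize("L,w,s", [(50, 10, 1), (51, 10, 3), (400, 300, 7)])
def test_window_count_matches_explicit_walk(L, w, s):
    starts = [i for i in range(0, L - w + 1, s)]
    assert n_windows(L, w, s) == len(starts)


# ------------------------------------------- sliding_window_enrichment

def test_planted_term_peaks_in_early_windows():
    rng = np.random.default_rng(0)
    n_exons = 400
    genes = {f"e{i:03d}": f"g{i:03d}" for i in range(n_exons)}
    catalog = catalog_of(genes)
    ranked = sorted(genes)  # rank i = exon i
    sets = {f"T{j}": set(rng.choice(sorted(set(genes.values())), 25,
                                    replace=False))
            for j in range(30)}
    planted = {f"g{i:03d}" for i in range(0, 60)}
    sets["PLANTED"] = planted
    table = sliding_window_enrichment(
        ranked, catalog, GeneSetCollection(sets), window=100, step=1,
        fdr_max=0.005,
    )
    assert table["window_index"].nunique() == n_windows(n_exons, 100, 1)
    hit = table[(table["term_id"] == "PLANTED") & table["significant"]]
    assert len(hit) > 0
    best = table[table["term_id"] == "PLANTED"].nsmallest(1, "fdr")
    assert best["window_index"].iloc[0] < 50
    # invariant: k <= min(K, n) everywhere
    assert (table["k"] <= table[["K", "n"]].min(axis=1)).all()


def test_window_longer_than_list_raises():
    catalog = catalog_of({"e1": "g1"})
    with pytest.raises(ValueError):
        sliding_window_enrichment(["e1"], catalog,
                                  GeneSetCollection({"T": {"g1"}}), window=5)


def test_significant_set_shrinks_with_stricter_fdr():
    rng = np.random.default_rng(3)
    genes = {f"e{i}": f"g{i}" for i in range(150)}
    catalog = catalog_of(genes)
    sets = {f"T{j}": set(rng.choice(sorted(set(genes.values())), 20,
                                    replace=False)) for j in range(20)}
    sets["P"] = {f"g{i}" for i in range(40)}
    loose = sliding_window_enrichment(sorted(genes, key=lambda e: int(e[1:])),
                                      catalog, GeneSetCollection(sets),
                                      window=50, fdr_max=0.05)
    strict = sliding_window_enrichment(sorted(genes, key=lambda e: int(e[1:])),
                                       catalog, GeneSetCollection(sets),
                                       window=50, fdr_max=0.005)
    assert strict["significant"].sum() <= loose["significant"].sum()


# ----------------------------------------------------- module_enrichment

def test_foreground_equal_background_is_null():
    genes = {f"e{i}": f"g{i}" for i in range(60)}
    catalog = catalog_of(genes)
    sets = GeneSetCollection({"T1": {f"g{i}" for i in range(20)},
                              "T2": {f"g{i}" for i in range(10, 40)}})
    table = module_enrichment({"M1": list(genes)}, catalog, sets)
    assert np.allclose(table["fold"], 1.0)
    assert not table["significant"].any()


def test_planted_fivefold_term_is_flagged():
    rng = np.random.default_rng(1)
    genes = {f"e{i:03d}": f"g{i:03d}" for i in range(500)}
    catalog = catalog_of(genes)
    universe = sorted(set(genes.values()))
    fg_exons = [f"e{i:03d}" for i in range(100)]
    planted = {f"g{i:03d}" for i in range(50)}  # half the foreground
    sets = {"PLANTED": planted | set(rng.choice(universe[200:], 0))}
    for j in range(20):
        sets[f"T{j}"] = set(rng.choice(universe, 40, replace=False))
    table = module_enrichment({"M1": fg_exons}, catalog,
                              GeneSetCollection(sets))
    row = table[table["term_id"] == "PLANTED"].iloc[0]
    assert row["fold"] == pytest.approx(5.0)
    assert row["significant"]


def test_term_outside_universe_excluded():
    genes = {"e1": "g1", "e2": "g2", "e3": "g3", "e4": "g4", "e5": "g5"}
    catalog = catalog_of(genes)
    sets = GeneSetCollection({"IN": {"g1", "g2", "g3", "g4", "g5"},
                              "OUT": {"x1", "x2", "x3", "x4", "x5"}})
    table = module_enrichment({"M": ["e1"]}, catalog, sets, min_term_genes=5)
    assert set(table["term_id"]) == {"IN"}


# ---------------------------------------------------- hexamer_enrichment

def test_planted_hexamer_is_top_ranked():
    fg, bg = simulate_sequences(60, 200, motif="TGCATG", seed=2)
    table = hexamer_enrichment(fg, bg)
    assert table.iloc[0]["hexamer"] == "TGCATG"
    assert table.iloc[0]["fdr"] < 0.05


def test_identical_foreground_background_is_null():
    fg, _ = simulate_sequences(50, 1, motif=None, seed=4)
    table = hexamer_enrichment(fg, fg)
    assert not (table["fdr"] < 0.05).any()


def test_short_and_ambiguous_sequences_contribute_nothing():
    table = hexamer_enrichment({"a": "ACGT", "b": "ACGNNNACG"},
                               {"c": "ACGTACGTACGT"})
    assert table["fg_with"].sum() == 0


def test_empty_fasta_rejected():
    with pytest.raises(ValueError):
        hexamer_enrichment({}, {"a": "ACGTACGT"})


# ------------------------------------------- cluster_enrichment_profiles

def make_profile_table(profiles: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for term, prof in profiles.items():
        for wi, fdr in enumerate(prof):
            rows.append({"term_id": term, "window_index": wi,
                         "fdr": fdr, "significant": fdr <= 0.05})
    return pd.DataFrame(rows)


def test_early_and_late_peaking_profiles_separate():
    early = 10.0 ** -np.array([8, 7, 6, 1, 1, 1], dtype=float)
    late = 10.0 ** -np.array([1, 1, 1, 6, 7, 8], dtype=float)
    profiles = {}
    for i in range(4):
        profiles[f"E{i}"] = early * (1 + 0.1 * i)
        profiles[f"L{i}"] = late * (1 + 0.1 * i)
    out = cluster_enrichment_profiles(make_profile_table(profiles),
                                      n_clusters=2)
    by_cluster = out.groupby("cluster")["term_id"].apply(
        lambda s: {t[0] for t in s})
    assert sorted(by_cluster.tolist(), key=len) == [{"E"}, {"L"}] or \
        set(map(frozenset, by_cluster)) == {frozenset("E"), frozenset("L")}


def test_identical_profiles_cluster_together_and_order_is_stable():
    prof = 10.0 ** -np.array([5, 4, 1], dtype=float)
    table = make_profile_table({"A": prof, "B": prof,
                                "C": 10.0 ** -np.array([1, 1, 6.0])})
    out1 = cluster_enrichment_profiles(table, n_clusters=2)
    out2 = cluster_enrichment_profiles(table.sample(frac=1, random_state=3),
                                       n_clusters=2)
    assert out1.loc[out1["term_id"] == "A", "cluster"].iloc[0] == \
        out1.loc[out1["term_id"] == "B", "cluster"].iloc[0]
    pd.testing.assert_frame_equal(out1, out2)
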