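"""Hypergeometric gene-set and hexamer enrichment analyses.

The sliding-window analysis walks a switch-time-ranked exon list with a
fixed-size window (300 exons by default, step 1), tests every gene set
against the deduplicated genes of each window with a hypergeometric
upper tail, and corrects jointly across all term × window tests with
Benjamini–Hochberg.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datamodel import ExonCatalog, GeneSetCollection
from .psi import bh_fdr

__all__ = [
    "hypergeom_upper",
    "sliding_window_enrichment",
    "module_enrichment",
    "hexamer_enrichment",
    "cluster_enrichment_profiles",
    "n_windows",
]


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(f"invalid hypergeometric arguments k={k} K={K} n={n} N={N}")
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def n_windows(length: int, window: int, step: int = 1) -> int:
    """Number of sliding windows over a list of the given length."""
    if window > length:
        raise ValueError("window exceeds list length")
    if step < 1:
        raise ValueError("step must be >= 1")
    return (length - window) // step + 1


def _term_matrix(gene_sets: GeneSetCollection, background: list[str]):
    """Boolean term × gene membership matrix over the background universe."""
    gene_pos = {g: i for i, g in enumerate(background)}
    terms = sorted(gene_sets.sets)
    M = np.zeros((len(terms), len(background)), dtype=bool)
    for ti, term in enumerate(terms):
        for g in gene_sets.sets[term]:
            if g in gene_pos:
                M[ti, gene_pos[g]] = True
    return terms, M


def sliding_window_enrichment(
    ranked_exons,
    catalog: ExonCatalog,
    gene_sets: GeneSetCollection,
    window: int = 300,
    step: int = 1,
    fdr_max: float = 0.005,
    background_genes=None,
    min_term_genes: int = 5,
) -> pd.DataFrame:
    """Per-window hypergeometric enrichment over a ranked exon list.

    Foreground of each window is the deduplicated set of genes of its
    exons; background defaults to all catalog genes. BH correction is
    joint across every (term, window) test. Returns a long table with
    columns term_id, window_index, start_rank, end_rank, k, K, n, N, p,
    fdr, significant.
    """
    ranked = list(ranked_exons)
    nw = n_windows(len(ranked), window, step)
    gene_of = catalog.gene_of()
    if background_genes is None:
        background_genes = sorted(set(gene_of))
    else:
        background_genes = sorted(set(background_genes))
    sets = gene_sets.restrict(set(background_genes), min_genes=min_term_genes)
    if len(sets) == 0:
        return pd.DataFrame(
            columns=["term_id", "window_index", "start_rank", "end_rank",
                     "k", "K", "n", "N", "p", "fdr", "significant"]
        )
    terms, M = _term_matrix(sets, background_genes)
    gene_pos = {g: i for i, g in enumerate(background_genes)}
    N = len(background_genes)
    K = M.sum(axis=1)

    rows_k = np.empty((nw, len(terms)), dtype=int)
    rows_n = np.empty(nw, dtype=int)
    bounds = []
    for wi in range(nw):
        start = wi * step
        exons = ranked[start: start + window]
        genes = {gene_of.get(e) for e in exons}
        idx = [gene_pos[g] for g in genes if g in gene_pos]
        fg = np.zeros(N, dtype=bool)
        fg[idx] = True
        rows_n[wi] = fg.sum()
        rows_k[wi] = M[:, fg].sum(axis=1)
        bounds.append((start + 1, start + window))

    # vectorized upper-tail p across every (window, term) cell
    p = stats.hypergeom.sf(
        rows_k - 1, N, K[None, :], rows_n[:, None]
    )
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    fdr = bh_fdr(p.ravel()).reshape(p.shape)
    records = []
    for wi, (s, e) in enumerate(bounds):
        for ti, term in enumerate(terms):
            records.append(
                (term, wi, s, e, int(rows_k[wi, ti]), int(K[ti]),
                 int(rows_n[wi]), N, p[wi, ti], fdr[wi, ti],
                 fdr[wi, ti] <= fdr_max)
            )
    return pd.DataFrame(
        records,
        columns=["term_id", "window_index", "start_rank", "end_rank",
                 "k", "K", "n", "N", "p", "fdr", "significant"],
    )


def module_enrichment(
    core_exons_by_module: dict[str, list[str]],
    catalog: ExonCatalog,
    gene_sets: GeneSetCollection,
    fdr_max: float = 0.05,
    background_genes=None,
    min_term_genes: int = 5,
) -> pd.DataFrame:
    """Standard per-module gene-set enrichment (one test per term per module)."""
    gene_of = catalog.gene_of()
    if background_genes is None:
        background_genes = sorted(set(gene_of))
    else:
        background_genes = sorted(set(background_genes))
    sets = gene_sets.restrict(set(background_genes), min_genes=min_term_genes)
    bg = set(background_genes)
    N = len(bg)
    records = []
    for module, exons in core_exons_by_module.items():
        if not exons:
            raise ValueError(f"module {module!r} has an empty foreground")
        fg = {gene_of.get(e) for e in exons} & bg
        n = len(fg)
        for term in sorted(sets.sets):
            term_genes = sets.sets[term]
            K = len(term_genes)
            k = len(fg & term_genes)
            p = hypergeom_upper(k, K, n, N)
            fold = (k / n) / (K / N) if n and K else np.nan
            records.append((module, term, k, K, n, N, fold, p))
    df = pd.DataFrame(
        records,
        columns=["module", "term_id", "k", "K", "n", "N", "fold", "p"],
    )
    if len(df):
        df["fdr"] = bh_fdr(df["p"].to_numpy())
        df["significant"] = df["fdr"] <= fdr_max
    return df


ALL_HEXAMERS = ["".join(h) for h in itertools.product("ACGT", repeat=6)]


def _hexamer_presence(seqs: dict[str, str]) -> np.ndarray:
    """Per-hexamer count of sequences containing >= 1 occurrence."""
    idx = {h: i for i, h in enumerate(ALL_HEXAMERS)}
    counts = np.zeros(len(ALL_HEXAMERS), dtype=int)
    for seq in seqs.values():
        seen = set()
        for i in range(len(seq) - 5):
            h = seq[i:i + 6]
            if "N" not in h:
                seen.add(h)
        for h in seen:
            counts[idx[h]] += 1
    return counts


def hexamer_enrichment(fg_seqs: dict[str, str],
                       bg_seqs: dict[str, str]) -> pd.DataFrame:
    """Hexamer enrichment in foreground vs background sequences.

    Counting is presence/absence per sequence (matching the
    hypergeometric sampling model): the population is all fg + bg
    sequences, successes are sequences containing the hexamer, draws
    are the foreground. Returns one row per hexamer sorted by p.
    """
    if not fg_seqs or not bg_seqs:
        raise ValueError("foreground and background FASTA must be non-empty")
    fg = _hexamer_presence(fg_seqs)
    bg = _hexamer_presence(bg_seqs)
    n_fg, n_bg = len(fg_seqs), len(bg_seqs)
    N = n_fg + n_bg
    K = fg + bg
    p = stats.hypergeom.sf(fg - 1, N, K, n_fg)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    df = pd.DataFrame(
        {
            "hexamer": ALL_HEXAMERS,
            "fg_with": fg,
            "bg_with": bg,
            "fg_total": n_fg,
            "bg_total": n_bg,
            "p": p,
            "fdr": bh_fdr(p),
        }
    )
    return df.sort_values(["p", "hexamer"], kind="mergesort").reset_index(drop=True)


def cluster_enrichment_profiles(
    table: pd.DataFrame, n_clusters: int = 2
) -> pd.DataFrame:
    """Group significant terms by the temporal shape of their enrichment.

    Each term with at least one significant window is represented by
    its −log10(fdr) vector across windows; average-linkage hierarchical
    clustering on Euclidean distance gives a deterministic leaf order
    and a flat cut into ``n_clusters`` groups.
    """
    sig_terms = sorted(table.loc[table["significant"], "term_id"].unique())
    profiles = (
        table[table["term_id"].isin(sig_terms)]
        .pivot(index="term_id", columns="window_index", values="fdr")
    )
    profiles = -np.log10(profiles)
    if len(profiles) == 0:
        return pd.DataFrame(columns=["term_id", "cluster", "leaf_order"])
    if len(profiles) == 1:
        return pd.DataFrame(
            {"term_id": profiles.index, "cluster": [1], "leaf_order": [0]}
        )
    link = hierarchy.linkage(pdist(profiles.to_numpy()), method="average")
    clusters = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    leaves = hierarchy.leaves_list(link)
    order = {profiles.index[leaf]: pos for pos, leaf in enumerate(leaves)}
    return pd.DataFrame(
        {
            "term_id": profiles.index,
            "cluster": clusters,
            "leaf_order": [order[t] for t in profiles.index],
        }
    ).sort_values("leaf_order").reset_index(drop=True)
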