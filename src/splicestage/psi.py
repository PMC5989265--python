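"""Ψ estimation from junction counts and differential splicing calls.

A cassette exon's inclusion isoform spans two exon–exon junctions while
the skipping isoform spans one, so raw inclusion-junction reads are
halved to put the two isoforms on the same per-transcript scale:
``i = inc_reads / 2``, ``coverage = i + skip_reads`` and
``Ψ = i / (i + skip_reads)``. Cells failing the coverage or the
binomial-standard-deviation filter are set to missing, never to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import PsiMatrix, SpliceCounts

__all__ = [
    "estimate_psi",
    "fisher_diff",
    "bh_fdr",
    "call_developmental",
    "DiffSpliceRecord",
]


def estimate_psi(
    counts: SpliceCounts,
    min_cov: float = 20.0,
    max_sd: float = 0.1,
    halve_inclusion: bool = True,
) -> PsiMatrix:
    """Estimate Ψ per (exon, sample) with coverage and SD filters.

    Parameters
    ----------
    counts
        Junction read counts.
    min_cov
        Minimum effective coverage ``i + s``; cells below are missing.
    max_sd
        Cells whose binomial standard deviation
        ``sqrt(Ψ(1−Ψ)/coverage)`` is >= this value are masked.
    halve_inclusion
        Divide inclusion-junction reads by two (the default, since the
        inclusion isoform contributes two junctions).
    """
    if min_cov <= 0:
        raise ValueError("min_cov must be positive")
    inc = counts.inc.to_numpy(dtype=float)
    skip = counts.skip.to_numpy(dtype=float)
    i = inc / 2.0 if halve_inclusion else inc
    cov = i + skip
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(cov > 0, i / np.where(cov > 0, cov, 1.0), np.nan)
        sd = np.sqrt(psi * (1.0 - psi) / np.where(cov > 0, cov, np.nan))
    mask = ~np.isfinite(psi) | (cov < min_cov) | (sd >= max_sd)
    psi = np.where(mask, np.nan, psi)
    cov = np.where(mask, np.nan, cov)
    idx, cols = counts.exon_ids, counts.samples
    return PsiMatrix(
        psi=pd.DataFrame(psi, index=idx, columns=cols),
        coverage=pd.DataFrame(cov, index=idx, columns=cols),
    )


@dataclass
class DiffSpliceRecord:
    """Differential splicing result for one exon between two conditions."""

    exon_id: str
    psi_a: float
    psi_b: float
    dpsi: float
    coverage_a: float
    coverage_b: float
    p: float
    fdr: float = np.nan
    called: bool = False


def _pooled_table(counts: SpliceCounts, halve: bool) -> pd.DataFrame:
    pooled = counts.pooled()
    i = pooled.inc["pooled"] / (2.0 if halve else 1.0)
    s = pooled.skip["pooled"]
    cov = i + s
    with np.errstate(invalid="ignore"):
        psi = i / cov
    return pd.DataFrame({"i": i, "s": s, "cov": cov, "psi": psi})


def fisher_diff(
    counts_a: SpliceCounts,
    counts_b: SpliceCounts,
    halve_inclusion: bool = True,
) -> pd.DataFrame:
    """Two-sided Fisher's exact test per exon on pooled junction counts.

    Replicates within each condition are pooled by summing counts. The
    2×2 table is built from (inclusion, skipping) counts after halving
    inclusion reads and rounding half-to-even. Returns a DataFrame
    indexed by exon_id with columns psi_a, psi_b, dpsi, coverage_a,
    coverage_b, p (fdr/called are filled in by callers via `bh_fdr`).
    """
    ta = _pooled_table(counts_a, halve_inclusion)
    tb = _pooled_table(counts_b, halve_inclusion)
    common = ta.index.intersection(tb.index)
    rows = []
    for exon in common:
        a, b = ta.loc[exon], tb.loc[exon]
        if not (np.isfinite(a["cov"]) and np.isfinite(b["cov"])):
            continue
        table = np.rint([[a["i"], a["s"]], [b["i"], b["s"]]]).astype(int)
        if table.sum() == 0 or table.sum(axis=0).min() == 0 or (
            table.sum(axis=1).min() == 0
        ):
            p = 1.0
        else:
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        psi_a = float(a["psi"]) if a["cov"] > 0 else np.nan
        psi_b = float(b["psi"]) if b["cov"] > 0 else np.nan
        dpsi = psi_b - psi_a if np.isfinite(psi_a) and np.isfinite(psi_b) else 0.0
        rows.append(
            {
                "exon_id": exon,
                "psi_a": psi_a,
                "psi_b": psi_b,
                "dpsi": dpsi,
                "coverage_a": float(a["cov"]),
                "coverage_b": float(b["cov"]),
                "p": min(p, 1.0),
            }
        )
    return pd.DataFrame(rows).set_index("exon_id") if rows else pd.DataFrame(
        columns=["psi_a", "psi_b", "dpsi", "coverage_a", "coverage_b", "p"]
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    diff: pd.DataFrame,
    min_cov: float = 20.0,
    fdr_max: float = 0.05,
    dpsi_min: float = 0.2,
) -> pd.DataFrame:
    """Attach BH FDR and the called flag to a `fisher_diff` table."""
    out = diff.copy()
    if len(out) == 0:
        out["fdr"] = []
        out["called"] = []
        return out
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["called"] = (
        (out["coverage_a"] >= min_cov)
        & (out["coverage_b"] >= min_cov)
        & (out["fdr"] <= fdr_max)
        & (out["dpsi"].abs() >= dpsi_min)
    )
    return out


def call_developmental(diff_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Flag exons regulated across an ordered stage series.

    ``diff_tables`` are called pairwise comparison tables (each with a
    boolean ``called`` and signed ``dpsi``). An exon is *regulated* if
    significant in at least one comparison and *monotonic* if all its
    significant changes share one sign.
    """
    if len(diff_tables) < 1:
        raise ValueError("need at least one pairwise comparison")
    all_exons = pd.Index([])
    for t in diff_tables:
        all_exons = all_exons.union(t.index)
    regulated = pd.Series(False, index=all_exons)
    monotonic = pd.Series(False, index=all_exons)
    signs: dict[str, set[int]] = {e: set() for e in all_exons}
    for t in diff_tables:
        called = t.index[t["called"].astype(bool)]
        regulated[called] = True
        for exon in called:
            signs[exon].add(1 if t.loc[exon, "dpsi"] > 0 else -1)
    for exon in all_exons:
        monotonic[exon] = regulated[exon] and len(signs[exon]) == 1
    return pd.DataFrame({"regulated": regulated, "monotonic": monotonic})
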