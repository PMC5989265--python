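"""Temporal co-splicing module detection over developmental Ψ profiles.

The pipeline follows weighted-correlation-network practice: an unsigned
adjacency ``a_uv = |pearson(u, v)|^power`` (power 3 by default), a
topological-overlap dissimilarity, average-linkage hierarchical
clustering with a static cut, a size filter, one eigenexon (first
principal component of the standardized member profiles) per module,
and iterative merging of modules whose eigenexons are closer than a
dissimilarity threshold (1 − correlation < 0.25 by default). Because
the adjacency is unsigned, each module splits into + and − member
groups by the sign of the exon–eigenexon correlation; core members are
those whose |correlation| clears the two-sided p < 0.001 critical value
for the number of time points (r ≈ 0.9 at nine points).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .datamodel import PsiMatrix

__all__ = [
    "adjacency",
    "critical_correlation",
    "CoSplicingModules",
    "detect_modules",
    "core_members",
]


def _as_values(psi) -> tuple[np.ndarray, pd.Index]:
    if isinstance(psi, PsiMatrix):
        psi = psi.psi
    if isinstance(psi, pd.DataFrame):
        return psi.to_numpy(dtype=float), psi.index
    arr = np.asarray(psi, dtype=float)
    return arr, pd.RangeIndex(len(arr))


def adjacency(psi, power: float = 3.0, signed: bool = False) -> pd.DataFrame:
    """Exon × exon adjacency ``|r|^power`` (or signed ``((1+r)/2)^power``).

    Rows must be complete (no missing time points) and non-constant; a
    zero-variance exon is a hard error naming the exon.
    """
    values, index = _as_values(psi)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    if not np.all(np.isfinite(values)):
        bad = index[~np.isfinite(values).all(axis=1)][0]
        raise ValueError(f"exon {bad!r} has missing values; drop incomplete rows first")
    sd = values.std(axis=1)
    if np.any(sd == 0):
        bad = index[sd == 0][0]
        raise ValueError(f"zero-variance exon: {bad!r}")
    r = np.corrcoef(values)
    r = np.clip(r, -1.0, 1.0)
    a = ((1.0 + r) / 2.0) ** power if signed else np.abs(r) ** power
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=index, columns=index)


def _tom_dissimilarity(adj: np.ndarray) -> np.ndarray:
    """Unsigned topological-overlap dissimilarity of an adjacency matrix."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return 1.0 - tom


def critical_correlation(n: int, alpha: float) -> float:
    """Smallest |r| significant at two-sided level ``alpha`` with n pairs.

    Uses the exact t-transform ``t = r sqrt(n−2)/sqrt(1−r²)`` with
    n − 2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("need n >= 3 observations")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n - 2
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(tcrit / np.sqrt(tcrit**2 + df))


def _eigenexon(values: np.ndarray) -> np.ndarray:
    """First PC of standardized profiles, unit norm, oriented so the
    mean correlation with member profiles is non-negative."""
    z = (values - values.mean(axis=1, keepdims=True)) / values.std(
        axis=1, keepdims=True
    )
    # PCA over time points: right singular vector of the standardized matrix
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    v = vt[0]
    v = v / np.linalg.norm(v)
    corrs = np.array([np.corrcoef(row, v)[0, 1] for row in z])
    if corrs.mean() < 0:
        v = -v
    return v


class CoSplicingModules(BaseEstimator, ClusterMixin):
    """Weighted-correlation-network detector of temporal splicing modules.

    Parameters
    ----------
    power : float
        Soft-thresholding exponent applied to |r| for the adjacency.
    min_size : int
        Minimum module size; smaller clusters are unassigned.
    merge_diss : float
        Modules whose eigenexons have dissimilarity (1 − |r|) below
        this are merged, eigenexons recomputed after each merge.
    cut_height : float
        Static dendrogram cut height on the dissimilarity scale (a
        deliberate simplification of dynamic tree cutting, validated by
        planted-module recovery).
    core_alpha : float
        Two-sided significance level defining core members.
    signed : bool
        Use a signed adjacency instead of the unsigned default.
    force_merge : sequence of (label, label) pairs, optional
        Manual module merges applied after automatic merging.

    Attributes
    ----------
    labels_ : ndarray of str — module label per exon ("" = unassigned).
    assignment_ : DataFrame with module, sign, eigen_corr, core per exon.
    eigenexons_ : DataFrame, module × time-point oriented unit eigenexons.
    """

    def __init__(
        self,
        power: float = 3.0,
        min_size: int = 30,
        merge_diss: float = 0.25,
        cut_height: float = 0.3,
        core_alpha: float = 0.001,
        signed: bool = False,
        force_merge=None,
    ):
        self.power = power
        self.min_size = min_size
        self.merge_diss = merge_diss
        self.cut_height = cut_height
        self.core_alpha = core_alpha
        self.signed = signed
        self.force_merge = force_merge

    def fit(self, X, y=None):
        values, index = _as_values(X)
        adj = adjacency(pd.DataFrame(values, index=index),
                        power=self.power, signed=self.signed).to_numpy()
        diss = _tom_dissimilarity(adj)
        condensed = squareform(diss, checks=False)
        link = hierarchy.linkage(condensed, method="average")
        raw = hierarchy.fcluster(link, t=self.cut_height, criterion="distance")

        # size filter, then relabel clusters deterministically by first member
        members: dict[int, np.ndarray] = {}
        for cl in np.unique(raw):
            idx = np.flatnonzero(raw == cl)
            if len(idx) >= self.min_size:
                members[cl] = idx
        if not members:
            warnings.warn("no cluster reaches min_size; empty assignment")
        groups = [members[cl] for cl in sorted(members, key=lambda c: members[c][0])]
        groups = self._merge(values, groups, self.merge_diss)
        if self.force_merge:
            groups = self._apply_forced(values, groups)

        labels = np.array([""] * len(values), dtype=object)
        eig_rows = {}
        for gi, idx in enumerate(groups):
            name = f"M{gi + 1}"
            labels[idx] = name
            eig_rows[name] = _eigenexon(values[idx])
        self.labels_ = labels
        self.eigenexons_ = pd.DataFrame(eig_rows).T
        if isinstance(X, (pd.DataFrame, PsiMatrix)):
            cols = X.psi.columns if isinstance(X, PsiMatrix) else X.columns
            if len(self.eigenexons_):
                self.eigenexons_.columns = cols
        self.n_timepoints_ = values.shape[1]
        self.assignment_ = self._score(values, index)
        return self

    # -- helpers ---------------------------------------------------------
    def _merge(self, values, groups, threshold):
        """Iteratively merge the closest eigenexon pair below threshold."""
        groups = [np.asarray(g) for g in groups]
        while len(groups) > 1:
            eigs = [_eigenexon(values[g]) for g in groups]
            best = None
            best_d = threshold
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    d = 1.0 - abs(np.corrcoef(eigs[i], eigs[j])[0, 1])
                    if d < best_d - 1e-12:
                        best_d = d
                        best = (i, j)
            if best is None:
                break
            i, j = best
            merged = np.sort(np.concatenate([groups[i], groups[j]]))
            groups = [g for gi, g in enumerate(groups) if gi not in (i, j)]
            groups.append(merged)
            groups.sort(key=lambda g: g[0])
        return groups

    def _apply_forced(self, values, groups):
        for pair in self.force_merge:
            ia, ib = (int(str(x).lstrip("M")) - 1 for x in pair)
            if ia >= len(groups) or ib >= len(groups):
                raise ValueError(f"force_merge pair {pair} out of range")
            merged = np.sort(np.concatenate([groups[ia], groups[ib]]))
            groups = [g for gi, g in enumerate(groups) if gi not in (ia, ib)]
            groups.append(merged)
            groups.sort(key=lambda g: g[0])
        return groups

    def _score(self, values, index):
        rcrit = critical_correlation(self.n_timepoints_, self.core_alpha)
        z = (values - values.mean(axis=1, keepdims=True)) / values.std(
            axis=1, keepdims=True
        )
        rows = []
        for i, exon in enumerate(index):
            mod = self.labels_[i]
            if not mod:
                rows.append(dict(module="", sign="", eigen_corr=np.nan, core=False))
                continue
            r = float(np.corrcoef(z[i], self.eigenexons_.loc[mod])[0, 1])
            rows.append(
                dict(
                    module=mod,
                    sign="+" if r >= 0 else "-",
                    eigen_corr=r,
                    core=bool(abs(r) >= rcrit),
                )
            )
        return pd.DataFrame(rows, index=index)


def detect_modules(psi, min_size: int = 30, merge_diss: float = 0.25,
                   **kwargs) -> CoSplicingModules:
    """Fit `CoSplicingModules` on a Ψ matrix and return the fitted detector."""
    return CoSplicingModules(min_size=min_size, merge_diss=merge_diss,
                             **kwargs).fit(psi)


def core_members(detector: CoSplicingModules, alpha: float = 0.001) -> pd.DataFrame:
    """Recompute the core flag of a fitted detector at level ``alpha``."""
    rcrit = critical_correlation(detector.n_timepoints_, alpha)
    out = detector.assignment_.copy()
    out["core"] = out["eigen_corr"].abs() >= rcrit
    out.loc[out["module"] == "", "core"] = False
    return out
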