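"""Shared domain containers for the splicing toolkit.

Conventions used throughout the package:

* Genomic intervals are 0-based, half-open (BED convention).
* Ψ (percent spliced in) values live in [0, 1]; a missing Ψ is NaN,
  never 0, because Ψ = 0 is a legitimate (fully skipped) estimate.
* The BED ``name`` field is the exon identifier and the single join key
  across count tables, Ψ matrices, catalogs and annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExonCatalog",
    "SpliceCounts",
    "PsiMatrix",
    "ReferenceAtlas",
    "GeneSetCollection",
]


@dataclass
class ExonCatalog:
    """Catalog of cassette exons.

    ``table`` is indexed by exon_id with columns
    ``gene_id, chrom, start, end, strand, novelty``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate exon_id in catalog: {dup!r}")
        bad = self.table["start"] >= self.table["end"]
        if bad.any():
            raise ValueError(
                f"exon {self.table.index[bad][0]!r} has start >= end"
            )
        strands = set(self.table["strand"].unique())
        if not strands <= {"+", "-"}:
            raise ValueError(f"invalid strand value(s): {strands - {'+', '-'}}")

    @property
    def exon_ids(self) -> pd.Index:
        return self.table.index

    def gene_of(self) -> pd.Series:
        """exon_id -> gene_id mapping."""
        return self.table["gene_id"]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SpliceCounts:
    """Junction read counts per (exon, sample).

    ``inc`` and ``skip`` are exon × sample DataFrames of non-negative
    counts; a missing (exon, sample) pair is NaN in both. ``inc`` is the
    raw total over the two inclusion junctions (no halving applied here).
    """

    inc: pd.DataFrame
    skip: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.inc.index.equals(self.skip.index) or not self.inc.columns.equals(
            self.skip.columns
        ):
            raise ValueError("inc and skip tables must share exons and samples")
        for name, df in (("inc", self.inc), ("skip", self.skip)):
            vals = df.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError(f"negative {name} read count")

    @property
    def exon_ids(self) -> pd.Index:
        return self.inc.index

    @property
    def samples(self) -> pd.Index:
        return self.inc.columns

    def pooled(self) -> "SpliceCounts":
        """Sum counts across samples into a single pooled pseudo-sample."""
        return SpliceCounts(
            inc=self.inc.sum(axis=1, min_count=1).to_frame("pooled"),
            skip=self.skip.sum(axis=1, min_count=1).to_frame("pooled"),
        )


@dataclass
class PsiMatrix:
    """Exon × sample inclusion levels with per-cell coverage.

    ``psi`` holds values in [0, 1] with NaN for missing cells;
    ``coverage`` is the matching effective junction-read coverage and is
    NaN exactly where ``psi`` is.
    """

    psi: pd.DataFrame
    coverage: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.psi.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("psi values must lie in [0, 1]")
        if self.coverage is None:
            self.coverage = self.psi.notna().astype(float) * np.nan
            self.coverage[self.psi.notna()] = np.inf
        else:
            if not self.coverage.index.equals(self.psi.index) or not (
                self.coverage.columns.equals(self.psi.columns)
            ):
                raise ValueError("coverage must match psi in shape and labels")
            mism = self.psi.isna() != self.coverage.isna()
            if mism.to_numpy().any():
                raise ValueError("coverage must be missing exactly where psi is")

    @property
    def exon_ids(self) -> pd.Index:
        return self.psi.index

    @property
    def sample_labels(self) -> list[str]:
        return list(self.psi.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.psi.shape

    def subset_exons(self, exon_ids) -> "PsiMatrix":
        keep = self.psi.index.intersection(pd.Index(exon_ids))
        return PsiMatrix(self.psi.loc[keep], self.coverage.loc[keep])

    def complete_rows(self) -> "PsiMatrix":
        """Drop exons with any missing sample."""
        keep = self.psi.notna().all(axis=1)
        return PsiMatrix(self.psi.loc[keep], self.coverage.loc[keep])


# Stage map used for the mouse cortex reference: embryonic ages through P7
# are individual stages; everything from P15 on collapses into stage 6
# because post-P15 profiles are nearly identical.
CORTEX_STAGE_MAP: dict[str, int] = {
    "E14.5": 1,
    "E16.5": 2,
    "P0": 3,
    "P4": 4,
    "P7": 5,
    "P15": 6,
    "P30": 6,
    "4mo": 6,
    "21mo": 6,
}

CORTEX_TIMEPOINTS: list[str] = list(CORTEX_STAGE_MAP)


@dataclass
class ReferenceAtlas:
    """Ordered developmental reference Ψ profiles with a stage map.

    Columns of ``psi_ref.psi`` are the reference time points in
    developmental order; ``stage_map`` sends each time-point label to an
    integer maturation stage 1..6 and must cover all six stages.
    """

    psi_ref: PsiMatrix
    stage_map: dict[str, int] = field(default_factory=lambda: dict(CORTEX_STAGE_MAP))

    def __post_init__(self) -> None:
        labels = self.psi_ref.sample_labels
        missing = [lb for lb in labels if lb not in self.stage_map]
        if missing:
            raise ValueError(f"time points missing from stage_map: {missing}")
        stages = {self.stage_map[lb] for lb in labels}
        if stages != set(range(1, max(stages) + 1)):
            raise ValueError("stage_map must be surjective onto 1..n_stages")

    @property
    def timepoints(self) -> list[str]:
        return self.psi_ref.sample_labels

    @property
    def exon_ids(self) -> pd.Index:
        return self.psi_ref.exon_ids

    def stages(self) -> np.ndarray:
        return np.array([self.stage_map[lb] for lb in self.timepoints])


@dataclass
class GeneSetCollection:
    """term_id -> set of gene_ids, with optional human-readable names."""

    sets: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [t for t, g in self.sets.items() if not g]
        if empty:
            raise ValueError(f"empty gene set(s): {empty[:3]}")

    def restrict(self, universe: set[str], min_genes: int = 1) -> "GeneSetCollection":
        """Intersect every term with ``universe``; drop terms below ``min_genes``."""
        kept = {
            t: g & universe
            for t, g in self.sets.items()
            if len(g & universe) >= min_genes
        }
        return GeneSetCollection(kept, {t: self.names.get(t, t) for t in kept})

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, term: str) -> bool:
        return term in self.sets
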