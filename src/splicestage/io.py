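"""Readers and writers for the toolkit's tabular, BED and FASTA formats.

Ψ matrices are plain TSV with exons as rows and samples as columns;
missing cells are empty strings. Coverage travels in a parallel TSV of
identical shape. Counts use a long layout:
``exon_id <TAB> sample <TAB> inc_reads <TAB> skip_reads``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .datamodel import (
    ExonCatalog,
    GeneSetCollection,
    PsiMatrix,
    SpliceCounts,
)

__all__ = [
    "read_psi_table",
    "write_psi_table",
    "read_count_table",
    "write_count_table",
    "read_exon_bed",
    "write_exon_bed",
    "read_gene_sets",
    "write_gene_sets",
    "read_fasta",
    "write_fasta",
    "to_one_based",
    "to_zero_based",
]


def read_psi_table(path, coverage_path=None) -> PsiMatrix:
    """Load a Ψ TSV (exon rows × sample columns; empty cell = missing).

    Values outside [0, 1] or non-numeric cells are hard errors that name
    the offending exon and sample. An optional parallel coverage TSV of
    identical shape may be supplied.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate exon_id {dup!r} in {path}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            exon = df.index[bad][0]
            raise ValueError(
                f"non-numeric Ψ cell at exon {exon!r}, sample {col!r}: "
                f"{df.loc[exon, col]!r}"
            )
        oob = (converted < 0) | (converted > 1)
        if oob.any():
            exon = converted.index[oob][0]
            raise ValueError(
                f"Ψ out of [0,1] at exon {exon!r}, sample {col!r}: "
                f"{converted[exon]}"
            )
        out[col] = converted
    coverage = None
    if coverage_path is not None:
        coverage = pd.read_csv(coverage_path, sep="\t", index_col=0)
        coverage = coverage.reindex(index=out.index, columns=out.columns)
        coverage = coverage.where(out.notna())
        coverage = coverage.fillna(np.nan)
        # cells quantified but lacking a coverage entry get +inf (trusted)
        coverage[out.notna() & coverage.isna()] = np.inf
    return PsiMatrix(out, coverage)


def write_psi_table(psi: PsiMatrix, path, coverage_path=None) -> None:
    psi.psi.to_csv(path, sep="\t", index_label="exon_id", na_rep="")
    if coverage_path is not None:
        cov = psi.coverage.where(psi.psi.notna())
        cov.to_csv(coverage_path, sep="\t", index_label="exon_id", na_rep="")


def read_count_table(path) -> SpliceCounts:
    """Load a long-format junction count TSV.

    Columns: exon_id, sample, inc_reads, skip_reads. Missing
    (exon, sample) pairs are allowed; negative counts are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"exon_id": str, "sample": str})
    required = {"exon_id", "sample", "inc_reads", "skip_reads"}
    if not required <= set(df.columns):
        raise ValueError(f"count table must have columns {sorted(required)}")
    if (df["inc_reads"] < 0).any() or (df["skip_reads"] < 0).any():
        row = df[(df["inc_reads"] < 0) | (df["skip_reads"] < 0)].iloc[0]
        raise ValueError(
            f"negative count for exon {row['exon_id']!r}, sample {row['sample']!r}"
        )
    inc = df.pivot(index="exon_id", columns="sample", values="inc_reads")
    skip = df.pivot(index="exon_id", columns="sample", values="skip_reads")
    # preserve file order of exons and samples (pivot sorts them)
    exon_order = df["exon_id"].drop_duplicates()
    sample_order = df["sample"].drop_duplicates()
    inc = inc.reindex(index=exon_order, columns=sample_order)
    skip = skip.reindex(index=exon_order, columns=sample_order)
    inc.index.name = skip.index.name = "exon_id"
    return SpliceCounts(inc=inc, skip=skip)


def write_count_table(counts: SpliceCounts, path) -> None:
    inc = counts.inc.stack().rename("inc_reads")
    skip = counts.skip.stack().rename("skip_reads")
    long = pd.concat([inc, skip], axis=1).reset_index()
    long.columns = ["exon_id", "sample", "inc_reads", "skip_reads"]
    long["inc_reads"] = long["inc_reads"].astype(int)
    long["skip_reads"] = long["skip_reads"].astype(int)
    long.to_csv(path, sep="\t", index=False)


def read_exon_bed(path) -> ExonCatalog:
    """Load a BED6 cassette-exon catalog (name field = exon_id).

    The score column doubles as a novelty flag: 0 = known, 1 = novel.
    An optional seventh column carries gene_id; otherwise gene_id is
    derived from the exon_id prefix before the last ``.``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: BED line has {len(fields)} fields, need >= 6"
                )
            chrom, start, end, name, score, strand = fields[:6]
            gene = fields[6] if len(fields) > 6 else name.rsplit(".", 1)[0]
            rows.append(
                {
                    "exon_id": name,
                    "gene_id": gene,
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "strand": strand,
                    "novelty": "novel" if score not in ("0", "0.0") else "known",
                }
            )
    table = pd.DataFrame(rows).set_index("exon_id")
    return ExonCatalog(table)


def write_exon_bed(catalog: ExonCatalog, path) -> None:
    with open(path, "w") as fh:
        for exon_id, row in catalog.table.iterrows():
            score = "1" if row["novelty"] == "novel" else "0"
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t{exon_id}\t"
                f"{score}\t{row['strand']}\t{row['gene_id']}\n"
            )


def read_gene_sets(path, names_path=None) -> GeneSetCollection:
    """Load a two-column gene_id <TAB> term_id TSV, inverted to term -> genes."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"],
                     dtype=str)
    sets: dict[str, set[str]] = {}
    for gene, term in zip(df["gene_id"], df["term_id"]):
        sets.setdefault(term, set()).add(gene)
    names: dict[str, str] = {}
    if names_path is not None:
        nm = pd.read_csv(names_path, sep="\t", header=None,
                         names=["term_id", "name"], dtype=str)
        names = dict(zip(nm["term_id"], nm["name"]))
    return GeneSetCollection(sets, names)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(collection.sets):
            for gene in sorted(collection.sets[term]):
                fh.write(f"{gene}\t{term}\n")


def read_fasta(path) -> dict[str, str]:
    """Load FASTA as an ordered id -> uppercase sequence dict."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"empty FASTA: {path}")
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based closed interval."""
    return start + 1, end


def to_zero_based(start1: int, end1: int) -> tuple[int, int]:
    """1-based closed -> 0-based half-open interval."""
    return start1 - 1, end1
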