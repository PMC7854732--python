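"""Readers and writers for every external format the pipeline touches.

Formats are deliberately minimal and text-only: BED (3+ columns) for peaks,
GMT for gene sets, and header-carrying TSV for the gene model, differential
tables, expression matrices, group labels and proteome tables. All readers
validate strictly and raise :class:`~cistromesig.types.FormatError` with the
offending line or identifier; downstream modules can then assume clean
domain objects.
"""
from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .types import (
    DifferentialTable,
    ExpressionMatrix,
    FormatError,
    GeneModel,
    GenomicInterval,
    PeakSet,
    ProteomeTable,
    SignatureSet,
)

# float format used by every writer so that identical inputs always produce
# byte-identical files
FLOAT_FMT = "%.6g"


def read_bed(path: str | os.PathLike, factor: str | None = None) -> PeakSet:
    """Read a BED file (>=3 tab-separated columns) into a sorted PeakSet.

    Coordinates are taken verbatim (BED is already 0-based half-open).
    Column 5, when present and numeric, is kept as the peak score. An empty
    file yields an empty PeakSet. The factor label defaults to the file's
    base name without extension.
    """
    if factor is None:
        factor = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: expected >=3 tab-separated columns at line {lineno}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-integer coordinates at line {lineno}"
                ) from exc
            if end <= start:
                raise FormatError(f"{path}: end <= start at line {lineno}")
            if start < 0:
                raise FormatError(f"{path}: negative start at line {lineno}")
            score = None
            if len(fields) >= 5:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
                else:
                    if score < 0:
                        score = None
            intervals.append(GenomicInterval(chrom, start, end, score))
    return PeakSet(factor, intervals)


def write_bed(peaks: PeakSet, path: str | os.PathLike) -> None:
    """Write a PeakSet as 3- or 5-column BED (name column '.' when scored)."""
    with open(path, "w") as fh:
        for iv in peaks:
            if iv.score is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{FLOAT_FMT % iv.score}\n"
                )


def read_gene_model(path: str | os.PathLike) -> GeneModel:
    """Read a gene-model TSV with columns gene_id, symbol, chrom, strand, tss."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "symbol", "chrom", "strand", "tss"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    try:
        return GeneModel(frame)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_gene_model(genes: GeneModel, path: str | os.PathLike) -> None:
    genes.frame.to_csv(path, sep="\t", index_label="gene_id")


def read_de_table(path: str | os.PathLike) -> DifferentialTable:
    """Read a differential-expression TSV (gene_id, log2fc, stat, pvalue, fdr)."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    try:
        return DifferentialTable(frame)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_de_table(de: DifferentialTable, path: str | os.PathLike) -> None:
    de.frame.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT)


def read_gmt(path: str | os.PathLike) -> SignatureSet:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ...

    The description column carries the signature's provenance text.
    """
    sigs = SignatureSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}: GMT line {lineno} needs name and description"
                )
            name, provenance, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            try:
                sigs.add(name, genes, provenance)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return sigs


def write_gmt(signatures: SignatureSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, sig in signatures.items():
            if "\t" in name:
                raise FormatError(f"signature name contains tab: {name!r}")
            prov = sig.provenance.replace("\t", " ") or "na"
            fh.write("\t".join([name, prov, *sig.genes]) + "\n")


def read_groups(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column TSV mapping sample -> group label."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in frame.columns or "group" not in frame.columns:
        raise FormatError(f"{path}: expected columns 'sample' and 'group'")
    if frame["sample"].duplicated().any():
        raise FormatError(f"{path}: duplicated sample ids")
    return dict(zip(frame["sample"], frame["group"]))


def read_expression(
    path: str | os.PathLike, groups_path: str | os.PathLike
) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene_id) plus group labels.

    Every sample column must have a label in the groups file; missing values
    are rejected (rank-based scoring downstream has no NA policy).
    """
    values = pd.read_csv(path, sep="\t", index_col="gene_id")
    groups = read_groups(groups_path)
    try:
        return ExpressionMatrix(values, groups)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression(
    expr: ExpressionMatrix,
    path: str | os.PathLike,
    groups_path: str | os.PathLike | None = None,
) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT)
    if groups_path is not None:
        expr.groups.rename_axis("sample").to_csv(groups_path, sep="\t")


def read_proteome(path: str | os.PathLike) -> ProteomeTable:
    """Read a proteome TSV: gene_id, n_unique_peptides, then one log2fc
    column per condition (every remaining numeric column is a condition)."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    conditions = [
        c for c in frame.columns if c not in ("gene_id", "n_unique_peptides")
    ]
    try:
        return ProteomeTable(frame, conditions)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_proteome(prot: ProteomeTable, path: str | os.PathLike) -> None:
    cols = ["n_unique_peptides", *prot.conditions]
    prot.frame[cols].to_csv(
        path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT
    )


def write_classes(classes: dict[str, str], path: str | os.PathLike) -> None:
    """Write a gene_id -> binding-class TSV (gene-model order preserved)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tclass\n")
        for gene_id, cls in classes.items():
            fh.write(f"{gene_id}\t{cls}\n")


def read_classes(path: str | os.PathLike) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in frame.columns or "class" not in frame.columns:
        raise FormatError(f"{path}: expected columns 'gene_id' and 'class'")
    if frame["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicated gene ids")
    return dict(zip(frame["gene_id"], frame["class"]))
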