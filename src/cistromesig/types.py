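"""Core in-memory containers shared by every pipeline stage.

All genomic coordinates are 0-based, half-open (BED convention). A gene is
identified by its ``gene_id`` string alone; no symbol aliasing is attempted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an external file or table violates its contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.score is not None and self.score < 0:
            raise ValueError(f"score must be non-negative, got {self.score}")

    def __len__(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def overlaps(x: GenomicInterval, y: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base.

    Half-open abutment (``x.end == y.start``) is *not* overlap: a shared
    base is required.
    """
    return x.chrom == y.chrom and max(x.start, y.start) < min(x.end, y.end)


class PeakSet:
    """A factor-labelled collection of peaks, kept sorted by (chrom, start, end)."""

    def __init__(self, factor: str, intervals: Iterable[GenomicInterval] = ()):
        self.factor = str(factor)
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=GenomicInterval.sort_key
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.factor == other.factor and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"PeakSet(factor={self.factor!r}, n={len(self)})"

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


class GeneModel:
    """One record per gene: id, symbol, chromosome, strand and a single TSS.

    The TSS column is 0-based. Genes with several annotated transcripts must
    be collapsed to one representative TSS before loading.
    """

    COLUMNS = ("symbol", "chrom", "strand", "tss")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.name != "gene_id":
            if "gene_id" in frame.columns:
                frame = frame.set_index("gene_id")
            else:
                raise FormatError("gene model requires a gene_id column")
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"gene model missing columns: {missing}")
        if frame.index.duplicated().any():
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene_id: {dups[:5]}")
        bad_strand = ~frame["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise FormatError(
                "strand must be + or -: "
                f"{frame.index[bad_strand].tolist()[:5]}"
            )
        frame["tss"] = frame["tss"].astype(np.int64)
        if (frame["tss"] < 0).any():
            raise FormatError("tss must be >= 0")
        self.frame = frame[list(self.COLUMNS)]

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.frame.index

    @property
    def gene_ids(self) -> list[str]:
        return self.frame.index.tolist()

    def record(self, gene_id: str) -> pd.Series:
        return self.frame.loc[gene_id]


class DifferentialTable:
    """Per-gene differential-expression summary for one contrast.

    Columns: ``log2fc`` (signed effect), ``stat`` (signed ranking statistic,
    e.g. a Wald statistic), ``pvalue`` and ``fdr`` in [0, 1].
    """

    COLUMNS = ("log2fc", "stat", "pvalue", "fdr")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.name != "gene_id":
            if "gene_id" in frame.columns:
                frame = frame.set_index("gene_id")
            else:
                raise FormatError("differential table requires a gene_id column")
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"differential table missing columns: {missing}")
        if frame.index.duplicated().any():
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene_id in differential table: {dups[:5]}")
        for col in ("pvalue", "fdr"):
            vals = frame[col].to_numpy(dtype=float)
            if np.any((vals < 0) | (vals > 1) | np.isnan(vals)):
                raise FormatError(f"{col} must lie in [0, 1]")
        self.frame = frame[list(self.COLUMNS)].astype(float)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def gene_ids(self) -> list[str]:
        return self.frame.index.tolist()


class ExpressionMatrix:
    """Genes x samples expression values plus a sample -> group label map."""

    def __init__(self, values: pd.DataFrame, groups: Mapping[str, str]):
        if values.index.duplicated().any():
            raise FormatError("duplicate gene ids in expression matrix")
        if values.columns.duplicated().any():
            raise FormatError("duplicate sample ids in expression matrix")
        if values.isna().to_numpy().any():
            raise FormatError(
                "expression matrix contains missing values; impute upstream"
            )
        unlabelled = [s for s in values.columns if s not in groups]
        if unlabelled:
            raise FormatError(f"unlabelled sample {unlabelled[0]}")
        self.values = values.astype(float)
        self.groups = pd.Series(
            {s: groups[s] for s in values.columns}, name="group"
        )

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()

    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class Signature:
    """An ordered, duplicate-free gene list with a free-text rule trace."""

    genes: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            seen: set[str] = set()
            dup = next(g for g in self.genes if g in seen or seen.add(g))
            raise ValueError(f"duplicate gene in signature: {dup}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)


class SignatureSet(dict):
    """Mapping of signature name -> :class:`Signature`."""

    def add(self, name: str, genes: Iterable[str], provenance: str = "") -> None:
        if name in self:
            raise ValueError(f"duplicate signature name: {name}")
        if "\t" in name:
            raise ValueError("signature name may not contain a tab")
        self[name] = Signature(tuple(genes), provenance)

    def validate_against(self, genes: GeneModel) -> None:
        universe = set(genes.gene_ids)
        for name, sig in self.items():
            stray = [g for g in sig.genes if g not in universe]
            if stray:
                raise ValueError(
                    f"signature {name} contains genes absent from the gene "
                    f"model: {stray[:5]}"
                )


class ProteomeTable:
    """Protein-level log2 fold changes per condition plus peptide evidence.

    ``conditions`` names the mutant-vs-wild-type ratio columns (one per SPOP
    mutant in the motivating design). ``n_unique_peptides`` is the per-protein
    count of distinct identifying peptides.
    """

    def __init__(self, frame: pd.DataFrame, conditions: list[str]):
        frame = frame.copy()
        if frame.index.name != "gene_id":
            if "gene_id" in frame.columns:
                frame = frame.set_index("gene_id")
            else:
                raise FormatError("proteome table requires a gene_id column")
        if frame.index.duplicated().any():
            raise FormatError("duplicate gene_id in proteome table")
        if "n_unique_peptides" not in frame.columns:
            raise FormatError("proteome table requires n_unique_peptides")
        missing = [c for c in conditions if c not in frame.columns]
        if missing:
            raise FormatError(f"proteome table missing condition columns: {missing}")
        if not conditions:
            raise FormatError("at least one condition column is required")
        pep = frame["n_unique_peptides"]
        if (pep != pep.astype(int)).any() or (pep < 0).any():
            raise FormatError("n_unique_peptides must be non-negative integers")
        frame["n_unique_peptides"] = pep.astype(int)
        self.frame = frame
        self.conditions = list(conditions)

    def __len__(self) -> int:
        return len(self.frame)
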