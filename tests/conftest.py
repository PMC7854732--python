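"""Shared fixtures: small hand-built domain objects and independent oracles.

The oracles here deliberately avoid the library's own code paths: the
classifier oracle is an all-pairs loop, the enrichment-score oracle is a
literal two-pass running sum, and the FDR oracle is the textbook step-up
recursion.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cistromesig.types import (
    DifferentialTable,
    GeneModel,
    GenomicInterval,
    PeakSet,
)


@pytest.fixture
def small_gene_model() -> GeneModel:
    frame = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4", "g5", "g6"],
            "symbol": [f"S{i}" for i in range(1, 7)],
            "chrom": ["chr1"] * 4 + ["chr2"] * 2,
            "strand": ["+", "-", "+", "+", "-", "+"],
            "tss": [10_000, 50_000, 90_000, 130_000, 10_000, 50_000],
        }
    )
    return GeneModel(frame)


def make_de_table(rows: dict[str, tuple[float, float]]) -> DifferentialTable:
    """Build a DifferentialTable from {gene: (log2fc, fdr)}; stat = log2fc,
    pvalue = fdr (sufficient for threshold-rule tests)."""
    frame = pd.DataFrame(
        {
            "gene_id": list(rows),
            "log2fc": [v[0] for v in rows.values()],
            "stat": [v[0] for v in rows.values()],
            "pvalue": [v[1] for v in rows.values()],
            "fdr": [v[1] for v in rows.values()],
        }
    )
    return DifferentialTable(frame)


def random_instance(
    rng: np.random.Generator, max_genes: int = 200, max_peaks: int = 500
) -> tuple[GeneModel, PeakSet, PeakSet]:
    """A random gene model plus unconstrained AR/ERG peak sets, for
    classifier-vs-oracle comparisons. Peaks are placed anywhere (including
    overlapping promoters of several genes), so all classifier branches are
    exercised."""
    n_genes = int(rng.integers(1, max_genes + 1))
    n_chroms = int(rng.integers(1, 4))
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    span = 40_000 + n_genes * 2_000
    frame = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n_genes)],
            "symbol": [f"S{i}" for i in range(n_genes)],
            "chrom": rng.choice(chroms, size=n_genes),
            "strand": rng.choice(["+", "-"], size=n_genes),
            "tss": rng.integers(0, span, size=n_genes),
        }
    )
    genes = GeneModel(frame)

    def peaks(factor: str) -> PeakSet:
        k = int(rng.integers(0, max_peaks + 1))
        starts = rng.integers(0, span, size=k)
        widths = rng.integers(1, 2_000, size=k)
        return PeakSet(
            factor,
            [
                GenomicInterval(str(c), int(s), int(s + w))
                for c, s, w in zip(rng.choice(chroms, size=k), starts, widths)
            ],
        )

    return genes, peaks("AR"), peaks("ERG")


def brute_force_classify(
    genes: GeneModel, ar: PeakSet, erg: PeakSet
) -> dict[str, str]:
    """All-pairs O(genes x peaks) classification oracle."""
    from cistromesig.annotate import promoter_window

    def hits(window, peaks):
        return [
            p
            for p in peaks
            if p.chrom == window.chrom
            and max(p.start, window.start) < min(p.end, window.end)
        ]

    out = {}
    for gene_id, rec in genes.frame.iterrows():
        w = promoter_window(rec["chrom"], rec["strand"], int(rec["tss"]))
        a, e = hits(w, ar), hits(w, erg)
        if not a and not e:
            cls = "NONE"
        elif a and not e:
            cls = "AR_ONLY"
        elif e and not a:
            cls = "ERG_ONLY"
        else:
            co = any(
                x.chrom == y.chrom and max(x.start, y.start) < min(x.end, y.end)
                for x in a
                for y in e
            )
            cls = "CO_BOUND" if co else "BOTH_DISJOINT"
        out[gene_id] = cls
    return out


def brute_force_es(
    values, gene_ids: list[str], signature: set[str], tau: float
) -> float:
    """Independent two-pass enrichment-score oracle with explicit loops."""
    n = len(values)
    ranks = rank_average(values)
    order = sorted(range(n), key=lambda i: -ranks[i])
    denom_in = sum(ranks[i] ** tau for i in range(n) if gene_ids[i] in signature)
    n_out = sum(1 for g in gene_ids if g not in signature)
    es = 0.0
    cum_in = 0.0
    cum_out = 0
    for i in order:
        if gene_ids[i] in signature:
            cum_in += ranks[i] ** tau
        else:
            cum_out += 1
        es += cum_in / denom_in - cum_out / n_out
    return es


def rank_average(values) -> list[float]:
    """Average ranks, 1..N with highest value = N, computed by hand."""
    n = len(values)
    idx = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[idx[j + 1]] == values[idx[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[idx[k]] = avg
        i = j + 1
    return ranks


def step_up_fdr(pvalues) -> list[float]:
    """Textbook Benjamini-Hochberg step-up oracle."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank_pos in range(n, 0, -1):
        i = order[rank_pos - 1]
        running_min = min(running_min, pvalues[i] * n / rank_pos)
        adjusted[i] = running_min
    return adjusted
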