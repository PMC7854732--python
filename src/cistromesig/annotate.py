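"""Promoter-centred peak annotation and AR/ERG co-binding classification.

Promoters are fixed windows of 1500 bp upstream to 500 bp downstream of each
gene's TSS, mirrored on the minus strand. A gene is called *co-bound* only
when an AR peak and an ERG peak in its promoter share at least one base;
genes whose promoters carry both factors at disjoint positions form their
own class (``BOTH_DISJOINT``) and enter no signature.
"""
from __future__ import annotations

from enum import Enum

from intervaltree import IntervalTree

from .types import GeneModel, GenomicInterval, PeakSet, overlaps

PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500
LOCUS_HALF_WIDTH = 5000


class BindingClass(str, Enum):
    NONE = "NONE"
    AR_ONLY = "AR_ONLY"
    ERG_ONLY = "ERG_ONLY"
    CO_BOUND = "CO_BOUND"
    BOTH_DISJOINT = "BOTH_DISJOINT"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


def promoter_window(
    chrom: str,
    strand: str,
    tss: int,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> GenomicInterval:
    """Promoter interval around a TSS, strand-aware and clipped at 0.

    Plus strand: ``[tss-upstream, tss+downstream)``. Minus strand: the
    reflection of that window about the TSS, ``[tss-downstream+1,
    tss+upstream+1)`` in half-open bookkeeping.
    """
    if strand == "+":
        start, end = tss - upstream, tss + downstream
    elif strand == "-":
        start, end = tss - downstream + 1, tss + upstream + 1
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")
    return GenomicInterval(chrom, max(0, start), end)


def locus_window(
    chrom: str, tss: int, half_width: int = LOCUS_HALF_WIDTH
) -> GenomicInterval:
    """Strand-independent ``[tss-half_width, tss+half_width)``, clipped at 0."""
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    return GenomicInterval(chrom, max(0, tss - half_width), tss + half_width)


def merge_peak_sets(a: PeakSet, b: PeakSet) -> PeakSet:
    """Union of two same-factor peak sets with overlapping peaks coalesced.

    Used to pool ChIP experiments from different time points into one
    cistrome. Only true overlaps (>=1 shared bp) are merged; book-ended
    intervals stay separate. Scores are dropped on coalescing.
    """
    if a.factor != b.factor:
        raise ValueError(
            f"cannot merge peak sets of different factors: {a.factor} vs {b.factor}"
        )
    merged: list[GenomicInterval] = []
    for iv in sorted(
        list(a) + list(b), key=GenomicInterval.sort_key
    ):
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return PeakSet(a.factor, merged)


def _build_trees(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, ivs in peaks.by_chrom().items():
        trees[chrom] = IntervalTree.from_tuples(
            (iv.start, iv.end, iv) for iv in ivs
        )
    return trees


def _hits(
    trees: dict[str, IntervalTree], window: GenomicInterval
) -> list[GenomicInterval]:
    tree = trees.get(window.chrom)
    if tree is None:
        return []
    return sorted(
        (node.data for node in tree.overlap(window.start, window.end)),
        key=GenomicInterval.sort_key,
    )


def classify_genes(
    genes: GeneModel,
    ar: PeakSet,
    erg: PeakSet,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> dict[str, BindingClass]:
    """Classify every gene by AR/ERG binding within its promoter window.

    Returns a total map over the gene model; classes are mutually exclusive
    and exhaustive:

    - ``NONE``: neither factor in the promoter;
    - ``AR_ONLY`` / ``ERG_ONLY``: exactly one factor present;
    - ``CO_BOUND``: both present with at least one AR/ERG peak pair sharing
      >=1 bp (mutual overlap is tested on the full peaks, not the clipped
      promoter fragments);
    - ``BOTH_DISJOINT``: both present but no mutually overlapping pair.
    """
    ar_trees = _build_trees(ar)
    erg_trees = _build_trees(erg)
    classes: dict[str, BindingClass] = {}
    for gene_id, rec in genes.frame.iterrows():
        window = promoter_window(
            rec["chrom"], rec["strand"], int(rec["tss"]), upstream, downstream
        )
        a_hits = _hits(ar_trees, window)
        e_hits = _hits(erg_trees, window)
        if not a_hits and not e_hits:
            cls = BindingClass.NONE
        elif a_hits and not e_hits:
            cls = BindingClass.AR_ONLY
        elif e_hits and not a_hits:
            cls = BindingClass.ERG_ONLY
        elif any(overlaps(x, y) for x in a_hits for y in e_hits):
            cls = BindingClass.CO_BOUND
        else:
            cls = BindingClass.BOTH_DISJOINT
        classes[gene_id] = cls
    return classes
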