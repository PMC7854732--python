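"""Promoter arithmetic, peak merging, and co-binding classification."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cistromesig.annotate import (
    BindingClass,
    classify_genes,
    locus_window,
    merge_peak_sets,
    promoter_window,
)
from cistromesig.types import GeneModel, GenomicInterval, PeakSet, overlaps
from .conftest import brute_force_classify, random_instance


class TestPromoterWindow:
    def test_plus_strand(self):
        w = promoter_window("chr1", "+", 10_000)
        assert (w.start, w.end) == (8_500, 10_500)

    def test_minus_strand_mirrored(self):
        w = promoter_window("chr1", "-", 10_000)
        assert (w.start, w.end) == (9_501, 11_501)

    def test_clipped_at_chromosome_start(self):
        w = promoter_window("chr1", "+", 100)
        assert (w.start, w.end) == (0, 600)

    def test_bad_strand(self):
        with pytest.raises(ValueError, match="strand"):
            promoter_window("chr1", "*", 100)

    @given(tss=st.integers(min_value=2_000, max_value=10**8))
    def test_minus_window_is_reflection_of_plus(self, tss):
        plus = promoter_window("chr1", "+", tss)
        minus = promoter_window("chr1", "-", tss)
        # reflect base b -> 2*tss - b; half-open [s, e) maps to [2t-e+1, 2t-s+1)
        assert (minus.start, minus.end) == (
            2 * tss - plus.end + 1,
            2 * tss - plus.start + 1,
        )

    @given(
        tss=st.integers(min_value=0, max_value=10**8),
        strand=st.sampled_from("+-"),
    )
    def test_window_contains_tss(self, tss, strand):
        w = promoter_window("chr1", strand, tss)
        assert w.start <= tss < w.end


class TestLocusWindow:
    def test_interior(self):
        w = locus_window("chr1", 20_000)
        assert (w.start, w.end) == (15_000, 25_000)

    def test_clipped(self):
        w = locus_window("chr1", 2_000)
        assert (w.start, w.end) == (0, 7_000)

    def test_zero_half_width_rejected(self):
        with pytest.raises(ValueError, match="half_width"):
            locus_window("chr1", 2_000, half_width=0)


class TestOverlaps:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("chr1", 100, 200), ("chr1", 199, 300), True),  # 1 bp shared
            (("chr1", 100, 200), ("chr1", 200, 300), False),  # abutment
            (("chr1", 100, 200), ("chr2", 100, 200), False),  # other chrom
            (("chr1", 100, 200), ("chr1", 150, 160), True),  # containment
        ],
    )
    def test_examples(self, a, b, expected):
        assert overlaps(GenomicInterval(*a), GenomicInterval(*b)) is expected


def _ps(factor, triples):
    return PeakSet(factor, [GenomicInterval(c, s, e) for c, s, e in triples])


class TestMergePeakSets:
    def test_overlap_coalesced(self):
        merged = merge_peak_sets(
            _ps("AR", [("chr1", 100, 200)]), _ps("AR", [("chr1", 150, 250)])
        )
        assert merged.intervals == [GenomicInterval("chr1", 100, 250)]

    def test_abutment_not_coalesced(self):
        merged = merge_peak_sets(
            _ps("AR", [("chr1", 100, 200)]), _ps("AR", [("chr1", 200, 300)])
        )
        assert len(merged) == 2

    def test_different_chromosomes_concatenated(self):
        merged = merge_peak_sets(
            _ps("AR", [("chr2", 0, 10)]), _ps("AR", [("chr1", 0, 10)])
        )
        assert [iv.chrom for iv in merged] == ["chr1", "chr2"]

    def test_factor_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different factors"):
            merge_peak_sets(_ps("AR", []), _ps("ERG", []))

    @settings(deadline=None, max_examples=50)
    @given(seed=st.integers(min_value=0, max_value=10**6))
    def test_idempotent_commutative_disjoint(self, seed):
        rng = np.random.default_rng(seed)
        def rand_ps():
            k = int(rng.integers(0, 30))
            return PeakSet(
                "AR",
                [
                    GenomicInterval(
                        f"chr{int(rng.integers(1, 3))}",
                        int(s := rng.integers(0, 5_000)),
                        int(s + rng.integers(1, 500)),
                    )
                    for _ in range(k)
                ],
            )
        a, b = rand_ps(), rand_ps()
        ab = merge_peak_sets(a, b)
        assert ab == merge_peak_sets(b, a)
        assert merge_peak_sets(ab, ab) == ab
        for x, y in zip(ab.intervals, ab.intervals[1:]):
            assert not overlaps(x, y)


class TestClassifyGenes:
    def _one_gene_model(self):
        return GeneModel(
            pd.DataFrame(
                {
                    "gene_id": ["g1"],
                    "symbol": ["S1"],
                    "chrom": ["chr1"],
                    "strand": ["+"],
                    "tss": [10_000],
                }
            )
        )

    def test_ar_only(self):
        genes = self._one_gene_model()
        classes = classify_genes(
            genes, _ps("AR", [("chr1", 9_000, 9_200)]), _ps("ERG", [])
        )
        assert classes["g1"] is BindingClass.AR_ONLY

    def test_co_bound_requires_mutual_overlap(self):
        genes = self._one_gene_model()
        classes = classify_genes(
            genes,
            _ps("AR", [("chr1", 9_000, 9_100)]),
            _ps("ERG", [("chr1", 9_050, 9_160)]),
        )
        assert classes["g1"] is BindingClass.CO_BOUND

    def test_both_disjoint_excluded_from_co_bound(self):
        # both factors in the promoter but never sharing a base: the gene is
        # recorded as bound by both yet kept out of the co-bound class
        genes = self._one_gene_model()
        classes = classify_genes(
            genes,
            _ps("AR", [("chr1", 8_600, 8_800)]),
            _ps("ERG", [("chr1", 9_000, 9_400)]),
        )
        assert classes["g1"] is BindingClass.BOTH_DISJOINT

    def test_mutual_overlap_outside_promoter_counts(self):
        # peaks partially enter the promoter; their mutual overlap lies
        # outside it — the rule tests overlap on the full peaks
        genes = self._one_gene_model()
        classes = classify_genes(
            genes,
            _ps("AR", [("chr1", 10_400, 11_000)]),
            _ps("ERG", [("chr1", 10_450, 11_050)]),
        )
        assert classes["g1"] is BindingClass.CO_BOUND

    def test_output_is_total_partition(self, small_gene_model):
        classes = classify_genes(
            small_gene_model,
            _ps("AR", [("chr1", 9_000, 9_200), ("chr2", 9_000, 9_300)]),
            _ps("ERG", [("chr2", 9_100, 9_250)]),
        )
        assert set(classes) == set(small_gene_model.gene_ids)
        assert all(isinstance(c, BindingClass) for c in classes.values())

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes, ar, erg = random_instance(rng, max_genes=60, max_peaks=120)
        fast = {g: str(c) for g, c in classify_genes(genes, ar, erg).items()}
        assert fast == brute_force_classify(genes, ar, erg)
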