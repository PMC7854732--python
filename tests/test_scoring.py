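"""Enrichment-score, rescaling, camera and Fisher-locus statistics."""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cistromesig.scoring import (
    aggregate_activity,
    camera_preranked,
    fisher_margin_pvalues,
    fisher_two_sided_p,
    locus_enrichment,
    rescale_scores,
    score_cohort,
    ssgsea_score,
)
from cistromesig.types import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    PeakSet,
    SignatureSet,
)
from .conftest import brute_force_es


class TestSsgseaScore:
    GENES = ["A", "B", "C", "D", "E"]
    EXPR = [5.0, 4.0, 3.0, 2.0, 1.0]

    def test_worked_example_tau_1(self):
        # running sums: .625, .2917, .6667, .3333, 0 -> 1.9167
        es = ssgsea_score(self.EXPR, self.GENES, {"A", "C"}, tau=1.0)
        assert es == pytest.approx(1.9167, abs=1e-4)

    def test_monotone_transform_invariance(self):
        es1 = ssgsea_score(self.EXPR, self.GENES, {"A", "C"}, tau=0.25)
        es2 = ssgsea_score(
            [math.exp(x) for x in self.EXPR], self.GENES, {"A", "C"}, tau=0.25
        )
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_full_signature_rejected(self):
        with pytest.raises(ValueError, match="every gene"):
            ssgsea_score(self.EXPR, self.GENES, set(self.GENES))

    def test_disjoint_signature_rejected(self):
        with pytest.raises(ValueError, match="no genes"):
            ssgsea_score(self.EXPR, self.GENES, {"Z"})

    def test_single_gene_profile_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ssgsea_score([1.0], ["A"], {"A"})

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 200))
        genes = [f"g{i}" for i in range(n)]
        values = rng.normal(size=n)
        if rng.random() < 0.5:  # exercise ties
            values = np.round(values, 1)
        m = int(rng.integers(1, n))
        sig = set(rng.choice(genes, size=m, replace=False))
        tau = float(rng.choice([0.0, 0.25, 1.0]))
        es = ssgsea_score(values, genes, sig, tau=tau)
        assert es == pytest.approx(
            brute_force_es(list(values), genes, sig, tau), abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_reversed_ranking_flips_sign_at_tau_0(self, seed):
        rng = np.random.default_rng(seed)
        n = 51
        genes = [f"g{i}" for i in range(n)]
        values = rng.permutation(n).astype(float)  # distinct ranks
        sig = set(rng.choice(genes, size=10, replace=False))
        es_fwd = ssgsea_score(values, genes, sig, tau=0.0)
        es_rev = ssgsea_score(-values, genes, sig, tau=0.0)
        assert es_fwd == pytest.approx(-es_rev, abs=1e-9)


class TestRescaleAggregate:
    def test_rescale_examples(self):
        np.testing.assert_allclose(rescale_scores([0, 5, 10]), [-1, 0, 1])
        np.testing.assert_allclose(
            rescale_scores([0, 5, 10], invert=True), [1, 0, -1]
        )

    def test_constant_input_warns_and_zeros(self):
        with pytest.warns(UserWarning, match="constant"):
            out = rescale_scores([3, 3, 3])
        np.testing.assert_allclose(out, [0, 0, 0])

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            rescale_scores([1.0])

    def test_aggregate_examples(self):
        np.testing.assert_allclose(aggregate_activity([1.0], [1.0]), [1.0])
        np.testing.assert_allclose(aggregate_activity([-1.0], [1.0]), [0.0])
        np.testing.assert_allclose(aggregate_activity([0.5], [-0.5]), [0.0])

    def test_sample_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different samples"):
            aggregate_activity([1.0, 0.0], [1.0])


class TestCameraPreranked:
    def _stats(self, in_vals, out_vals):
        vals = list(in_vals) + list(out_vals)
        idx = [f"in{i}" for i in range(len(in_vals))] + [
            f"out{i}" for i in range(len(out_vals))
        ]
        sig = [f"in{i}" for i in range(len(in_vals))]
        return pd.Series(vals, index=idx), sig

    def test_zero_delta_gives_p_one(self):
        stats, sig = self._stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        res = camera_preranked(stats, sig, rho=0.1)
        assert res.effect == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_rho_zero_equals_pooled_t_test(self, seed):
        rng = np.random.default_rng(seed)
        in_vals = rng.normal(0.5, 1, size=int(rng.integers(3, 40)))
        out_vals = rng.normal(0, 1, size=int(rng.integers(3, 200)))
        stats, sig = self._stats(in_vals, out_vals)
        res = camera_preranked(stats, sig, rho=0.0)
        ref = sps.ttest_ind(in_vals, out_vals, equal_var=True)
        assert res.pvalue == pytest.approx(ref.pvalue, abs=1e-9)

    def test_variance_inflation_shrinks_significance(self):
        rng = np.random.default_rng(3)
        stats, sig = self._stats(rng.normal(1, 1, 30), rng.normal(0, 1, 300))
        ps = [camera_preranked(stats, sig, rho=r).pvalue for r in (0.0, 0.1, 0.5)]
        assert ps[0] < ps[1] < ps[2]

    def test_degenerate_variance_rejected(self):
        stats, sig = self._stats([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="degenerate variance"):
            camera_preranked(stats, sig)

    def test_direction_is_sign_of_delta(self):
        stats, sig = self._stats([-2.0, -3.0, -1.0], [0.0, 0.1, -0.1, 0.2])
        assert camera_preranked(stats, sig).direction == -1


def exact_fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration in exact integer
    arithmetic (pmf numerators over a common denominator C(N, n); the same
    1e-7 relative tie fuzz as the float implementation, applied exactly)."""
    N, K, n = a + b + c + d, a + c, a + b
    lo, hi = max(0, n - (N - K)), min(K, n)
    nums = [math.comb(K, k) * math.comb(N - K, n - k) for k in range(lo, hi + 1)]
    obs = nums[a - lo]
    total = sum(v for v in nums if v * 10**7 <= obs * (10**7 + 1))
    return min(1.0, total / math.comb(N, n))


class TestFisherLocus:
    def test_matches_scipy_fisher_exact(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            t = rng.integers(0, 40, size=4)
            assert fisher_two_sided_p(*t) == pytest.approx(
                sps.fisher_exact(t.reshape(2, 2))[1], abs=1e-12
            )

    def test_matches_exact_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            t = rng.integers(0, 15, size=4)
            assert fisher_two_sided_p(*t) == pytest.approx(
                exact_fisher_oracle(*t), abs=1e-10
            )

    def _locus_setup(self, bound_in, unbound_in, bound_out, unbound_out):
        n = bound_in + unbound_in + bound_out + unbound_out
        frame = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "symbol": [f"S{i}" for i in range(n)],
                "chrom": ["chr1"] * n,
                "strand": ["+"] * n,
                "tss": [20_000 * (i + 1) for i in range(n)],
            }
        )
        genes = GeneModel(frame)
        sig = [f"g{i}" for i in range(bound_in + unbound_in)]
        bound = [f"g{i}" for i in range(bound_in)] + [
            f"g{i}" for i in range(bound_in + unbound_in,
                                   bound_in + unbound_in + bound_out)
        ]
        peaks = PeakSet(
            "Z",
            [
                GenomicInterval("chr1", t - 100, t + 100)
                for t in frame.set_index("gene_id").loc[bound, "tss"]
            ],
        )
        return peaks, genes, sig

    def test_worked_odds_ratio_and_hypergeometric_p(self):
        peaks, genes, sig = self._locus_setup(8, 2, 10, 80)
        res = locus_enrichment(peaks, genes, sig)
        assert res.effect == pytest.approx(32.0)
        assert res.pvalue == pytest.approx(exact_fisher_oracle(8, 2, 10, 80), abs=1e-10)
        assert res.direction == 1

    def test_equal_bound_fraction_gives_or_one(self):
        peaks, genes, sig = self._locus_setup(5, 5, 20, 20)
        res = locus_enrichment(peaks, genes, sig)
        assert res.effect == pytest.approx(1.0)

    def test_zero_cell_uses_haldane_correction(self):
        peaks, genes, sig = self._locus_setup(6, 0, 10, 30)
        res = locus_enrichment(peaks, genes, sig)
        assert np.isfinite(res.effect)
        assert res.effect == pytest.approx((6.5 * 30.5) / (0.5 * 10.5))

    def test_empty_signature_rejected(self):
        peaks, genes, _ = self._locus_setup(2, 2, 2, 2)
        with pytest.raises(ValueError, match="empty signature"):
            locus_enrichment(peaks, genes, [])


class TestScoreCohort:
    def _cohort(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(100)]
        spop = genes[:10]
        erg = genes[10:20]
        mat = rng.normal(size=(100, 8))
        mat[:10, :4] += 2.0   # SPOP-up genes high in first 4 samples
        mat[10:20, 4:] += 2.0  # ERG-up genes high in the rest
        values = pd.DataFrame(
            mat,
            index=pd.Index(genes, name="gene_id"),
            columns=[f"S{i}" for i in range(8)],
        )
        groups = {f"S{i}": ("SPOP-like" if i < 4 else "ERG-like") for i in range(8)}
        sigs = SignatureSet()
        sigs.add("SPOP_up", spop)
        sigs.add("ERG_up", erg)
        return ExpressionMatrix(values, groups), sigs

    def test_aggregate_separates_planted_groups(self):
        expr, sigs = self._cohort()
        table = score_cohort(expr, sigs)
        means = table.groupby("group")["aggregate"].mean()
        assert means["SPOP-like"] > means["ERG-like"]
        assert table["aggregate"].between(-1, 1).all()
        assert table[["rescaled_SPOP_up", "rescaled_ERG_up_inverted"]].to_numpy().max() <= 1.0

    def test_aggregate_is_mean_of_components(self):
        expr, sigs = self._cohort()
        table = score_cohort(expr, sigs)
        np.testing.assert_allclose(
            table["aggregate"],
            (table["rescaled_SPOP_up"] + table["rescaled_ERG_up_inverted"]) / 2,
        )

    def test_missing_signature_rejected(self):
        expr, sigs = self._cohort()
        with pytest.raises(KeyError):
            score_cohort(expr, sigs, spop_set="nope")
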