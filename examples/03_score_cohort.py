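"""Score a two-subtype cohort with the aggregate SPOP/ERG activity score.

Simulates a 20+20-sample cohort with planted SPOP-up/ERG-up signatures,
scores every sample (rank running sum, tau=0.25), rescales to [-1, 1] with
the ERG-up score inverted, and averages into one activity score per sample.
"""
from scipy.stats import mannwhitneyu

from cistromesig import score_cohort
from cistromesig.simulate import (
    SimConfig,
    pick_subtype_genes,
    simulate_expression,
    simulate_gene_model,
)
from cistromesig.types import SignatureSet

cfg = SimConfig(seed=3)
genes = simulate_gene_model(cfg)
spop_up, erg_up = pick_subtype_genes(genes, cfg)
expr, _ = simulate_expression(genes, spop_up, erg_up, cfg)

sigs = SignatureSet()
sigs.add("SPOP_up", spop_up)
sigs.add("ERG_up", erg_up)
table = score_cohort(expr, sigs)

means = table.groupby("group")["aggregate"].mean()
a = table.loc[table["group"] == "SPOP-like", "aggregate"]
b = table.loc[table["group"] == "ERG-like", "aggregate"]
p = mannwhitneyu(a, b, alternative="greater").pvalue
print(table.head())
print(f"\nmean aggregate: SPOP-like={means['SPOP-like']:+.3f}, "
      f"ERG-like={means['ERG-like']:+.3f}")
print(f"one-sided rank-sum p = {p:.3g}")
# An aggregate near +1 reads "SPOP-mutant-like" (high SPOP-up activity, low
# ERG-up activity); near -1 reads "ERG-fused-like". The rank-sum p states
# how cleanly the score separates the two planted subtypes.
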