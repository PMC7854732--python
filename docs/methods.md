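# Methods

This note documents the statistical procedures implemented in
`cistromesig`, their assumptions, the tunable parameters, the synthetic
data model used to exercise them, and the design decisions taken where the
procedures themselves leave room.

## Coordinates and gene identity

All genomic intervals are 0-based half-open (BED convention), including
the gene-model TSS column; one convention everywhere removes whole classes
of off-by-one errors. Genes are matched by `gene_id` string only — no
symbol aliasing — and a gene model must already be collapsed to a single
representative TSS per gene (when annotations offer several transcripts,
that choice belongs upstream).

## Promoter windows and co-binding classes

The promoter is the fixed window from 1500 bp upstream to 500 bp
downstream of the TSS. On the + strand that is `[tss−1500, tss+500)`; on
the − strand the window is the reflection about the TSS,
`[tss−499, tss+1501)` in half-open bookkeeping; both are clipped at
coordinate 0. The mirrored-window arithmetic is our choice; the window
size is part of the procedure.

Peak sets from different time points of the same experiment are pooled by
coalescing any peaks that share at least one base. Book-ended intervals
(`end == start`) are not merged: "at least 1 bp" demands a shared base,
and the same strictness applies everywhere an overlap is tested.

Each gene receives exactly one of five classes from the AR and ERG peaks
overlapping its promoter: `NONE`, `AR_ONLY`, `ERG_ONLY`, `CO_BOUND` (some
AR/ERG peak pair overlaps mutually by ≥1 bp), or `BOTH_DISJOINT` (both
factors present, no mutually overlapping pair). `BOTH_DISJOINT` is kept as
a first-class output because such genes are bona fide double-bound yet,
by the strict co-binding rule, belong to neither an "only" class nor the
co-bound class; they enter no signature. Mutual overlap is tested on the
full peaks, not on their promoter-clipped fragments, so a pair whose
shared bases lie just outside the window still counts as co-bound when
both peaks reach into the promoter. Classification uses an interval tree
per chromosome; tests assert exact agreement with an all-pairs oracle.

## Signature construction

Let `sigUp(c)`/`sigDown(c)` be the genes with `fdr < 0.05` and positive
(negative) log₂FC in contrast `c`; inequalities are strict, ties at the
threshold are excluded, and genes absent from a contrast count as not
significant (upstream independent filtering routinely drops low-count
genes — silence is absence of evidence, not evidence of no effect).
Sign conventions: in the DHT contrast, positive log₂FC means
DHT-induced; in the ERG-silencing contrast, a gene that falls upon
knockdown is ERG-induced and one that rises is ERG-repressed.

The five binding-informed signatures:

    DHT_induced            = AR_ONLY  ∩ sigUp(dht)      \ sigDown(erg_kd)
    DHT_repressed          = AR_ONLY  ∩ sigDown(dht)    \ sigUp(erg_kd)
    ERG_induced            = ERG_ONLY ∩ sigDown(erg_kd) \ sigUp(dht)
    ERG_repressed          = ERG_ONLY ∩ sigUp(erg_kd)   \ sigDown(dht)
    CoBound_DHTind_ERGrep  = CO_BOUND ∩ sigUp(dht)      ∩ sigUp(erg_kd)

The cross-exclusions are applied symmetrically to the AR-side and ERG-side
sets — the only reading under which the four "only" signatures stay
mutually consistent — and use the same FDR threshold as inclusion. The
exclusions can make final signature sizes non-monotone in the threshold,
so monotonicity is only asserted (and only holds) at the sigUp/sigDown
level.

Subtype signatures from a SPOP-mutant vs ERG-fused contrast use
`log₂FC > 1` (resp. `< −1`) with `fdr < 0.05`.

Benjamini–Hochberg adjustment is delegated to
`scipy.stats.false_discovery_control` behind a validating wrapper and is
property-tested against a hand-written step-up recursion.

## Single-sample activity scoring

For one sample, genes are ranked 1..N by expression (highest = N; tied
values receive average ranks) and traversed in decreasing rank, ties
broken by position in the gene list — deterministic and documented. With
in-set weights `rank^τ`, the score is

    ES = Σ_i [ P_in(i) − P_out(i) ],

the accumulated difference between the weighted in-set CDF and the uniform
out-of-set CDF over all N positions. τ defaults to 0.25, the established
default for this family of scores (the procedure's source names the
package but not the exponent); it is exposed as a parameter. The score is
rank-based and therefore invariant under strictly monotone transforms of
the expression values, which also makes the pipeline indifferent to
whether scores were pre-normalized by a global score range: the subsequent
rescale absorbs any affine transformation.

Raw per-signature scores are min–max rescaled to [−1, 1] **within the
scored cohort** (the procedure rescales per-cohort score vectors; no
fixed constants exist), with the ERG-up score additionally inverted so
that +1 always reads "SPOP-mutant-like". A constant score vector has no
dynamic range and maps to zeros with a warning. The aggregate activity is
the per-sample mean of the two rescaled components, hence also in [−1, 1].
No cross-sample normalization is applied before rescaling — the rescale
subsumes it.

## Enrichment statistics

**Competitive pre-ranked test.** For a signature of m genes among N ranked
statistics, with `delta` the in/out mean difference and `s²` the pooled
two-group variance, the statistic is

    t = delta / ( s · sqrt( VIF/m + 1/(N−m) ) ),   VIF = 1 + (m−1)ρ,

with df = N−2 and a two-sided p; direction is reported separately as
sign(delta). ρ defaults to 0.1. At ρ = 0 this is exactly the pooled
two-sample t-test (asserted to 1e-9 against an independent t-test); |t|
decreases monotonically in ρ. A zero pooled variance is an error, not a
p of 0.

**TSS-locus peak enrichment.** A gene is "bound" iff ≥1 peak overlaps its
strand-independent `[tss−5000, tss+5000)` window. The in-set × bound 2×2
table is tested two-sided by Fisher's exact test; the odds ratio uses the
Haldane–Anscombe +0.5 correction when any cell is zero. This is a
deliberate simplification of locus-based regression approaches that
adjust for locus length — with a fixed 10 kb locus per gene there is no
length variation to adjust for, but no spline adjustment of any kind is
attempted; the divergence is documented here. The two-sided p is computed
by a vectorized hypergeometric enumeration (with the conventional 1e-7
relative tie fuzz) that agrees with `scipy.stats.fisher_exact` to
machine precision and with an exact integer-arithmetic enumeration over
every 2×2 table of total ≤60.

## Substrate nomination

Proteome hygiene: keep proteins with ≥2 unique peptides; median-normalize
every condition column (idempotent); contaminant/decoy removal is assumed
done upstream, with an optional flag-column drop provided. Protein log₂
fold changes are averaged across the mutant conditions; a per-condition
consistency mode (hit in ≥k conditions) is available as an option.

A candidate satisfies `mean protein log₂FC > 0.5` AND (`rna_fdr ≥ 0.05`
OR `|rna log₂FC| < 0.25`). The numeric thresholds are this package's
defaults — the criterion originates as a qualitative scatter-plot filter
with no published cutoffs — and all are exposed as parameters. Genes
missing from the RNA table are decided on the protein criterion alone and
flagged `no-rna`. Output order is by protein effect descending with
gene-id tie-break, so results are invariant to input row order.

## Synthetic data model

The generator produces every pipeline input with planted truth:

- **Gene model** — 5000 genes on 5 toy chromosomes, ≥10 kb spacing, so
  promoter windows never overlap and planted classes are unambiguous.
- **Cistrome** — class fractions NONE 0.60 / AR_ONLY 0.15 / ERG_ONLY 0.15
  / CO_BOUND 0.06 / BOTH_DISJOINT 0.04; peak widths ~Normal(300, 50) bp,
  clipped to fit the promoter. These fractions and widths are this
  package's realism choices (a majority of genes unbound; co-binding the
  smallest class; typical TF peak widths); no external values exist for
  them. Peaks are placed inside each gene's promoter to realize its class
  exactly, so the classifier closes the loop at 100% agreement.
- **Perturbation contrasts** — bound classes respond deterministically
  (AR_ONLY split half induced/half repressed; ERG_ONLY likewise; co-bound
  and disjoint genes respond in both contrasts), plus a 10% indirect-
  responder fraction among unbound genes that must not leak into the
  binding-gated signatures. Observed `log₂FC ~ Normal(±2, 0.25)`,
  `stat = log2fc/se` (a Wald-type statistic), normal two-sided p, BH FDR.
- **Cohort** — 20+20 samples; planted SPOP-up (n=443) and ERG-up (n=359)
  gene sets shifted ±1.0 on a Normal(8, 2) baseline with Normal(0, 0.5)
  noise, mirrored between groups. The signature sizes mirror the scale of
  clinically derived subtype signatures.
- **Proteome** — 1000 proteins; 50 planted discordant substrates (protein
  +1.0, mRNA 0) and 50 matched concordant genes (+1.0 in both layers, to
  probe specificity); noise s.d. 0.15; ~10% of null proteins carry <2
  unique peptides to exercise the evidence filter.

Noise is Gaussian on the log₂ scale rather than negative-binomial at the
count level: the pipeline consumes DE summary tables, never counts, so
count-level realism would add nothing the tests could detect. This is a
known limitation — passing tests demonstrate correctness of the set
algebra, scoring and decision rules under well-behaved noise, not
robustness to count overdispersion, normalization artifacts, batch
effects or the correlated genes real cohorts contain. One global seed
fans out to fixed per-generator substreams, so any single stage is
reproducible in isolation and complete runs are byte-identical under a
fixed seed.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the cohort-separation check
at the full default conditions (5000 genes, 20+20 samples, 100 seeds),
signature recovery on 2000-gene genomes over 50 seeds, substrate recovery
on 1500-gene genomes over 100 seeds, and the classifier/score oracle
comparisons on instances of up to 200 genes/500 peaks — sizes chosen so
the whole suite completes in a few minutes on one CPU while keeping every
planted-truth bound at its stated strength.

## Known limitations

- Enhancer (non-promoter) binding is never assigned to genes; only the
  fixed promoter and ±5 kb locus windows are used.
- Whether a partially promoter-overlapping peak should be clipped before
  the mutual-overlap test is ambiguous in the source procedure; this
  implementation tests mutual overlap on full peaks and documents it.
- The aggregate activity score is cohort-relative (min–max over the scored
  samples); scores are not comparable across cohorts without joint
  rescaling.
- Substrate-nomination thresholds are package defaults, not published
  constants; sensitivity/specificity claims hold under the synthetic
  noise model above.
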