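"""Single-sample signature activity and gene-set enrichment statistics.

Three statistics live here:

- a single-sample enrichment score (ssGSEA-style weighted rank running sum)
  with per-cohort rescaling to [-1, 1] and an aggregate SPOP/ERG activity
  score (mean of the SPOP-up score and the inverted ERG-up score);
- a competitive pre-ranked gene-set test with a variance inflation factor
  ``1 + (m-1)*rho`` accounting for inter-gene correlation;
- a TSS-locus peak enrichment (2x2 Fisher exact on bound/unbound x in/out
  of set, locus = TSS +/- 5 kb).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as _stats

from .annotate import LOCUS_HALF_WIDTH, locus_window
from .signatures import bh_adjust
from .types import ExpressionMatrix, GeneModel, PeakSet, SignatureSet

DEFAULT_TAU = 0.25
DEFAULT_RHO = 0.1


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's enrichment against one ranking or cistrome."""

    name: str
    effect: float  # mean rank-statistic difference, or odds ratio
    pvalue: float
    fdr: float | None
    direction: int  # sign of the effect (+1 enriched up / -1 down, 0 none)
    n_set: int


def _ranks_and_order(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average ranks (1..N, highest value = N) and traversal order
    (decreasing rank; ties broken by position in the input gene order)."""
    ranks = _stats.rankdata(values, method="average")
    order = np.argsort(-ranks, kind="stable")
    return ranks, order


def ssgsea_score(
    values,
    gene_ids: list[str],
    signature_genes,
    tau: float = DEFAULT_TAU,
) -> float:
    """Single-sample enrichment score of one signature in one sample.

    Genes are ranked by expression (1..N, highest = N, ties averaged) and
    traversed in decreasing rank. The score is the sum over all positions of
    the difference between the weighted in-set cumulative distribution
    (weights ``rank**tau``) and the uniform out-of-set cumulative
    distribution. Rank-based: invariant under strictly monotone transforms
    of the expression values.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n != len(gene_ids):
        raise ValueError("values and gene_ids length mismatch")
    if n < 2:
        raise ValueError("at least 2 genes are required")
    in_set = np.isin(gene_ids, list(signature_genes))
    m = int(in_set.sum())
    if m == 0:
        raise ValueError("signature shares no genes with the expression profile")
    if m == n:
        raise ValueError("signature covers every gene; score is undefined")
    ranks, order = _ranks_and_order(values)
    return _es_from_ranks(ranks, order, in_set, tau)


def _es_from_ranks(
    ranks: np.ndarray, order: np.ndarray, in_set: np.ndarray, tau: float
) -> float:
    in_ord = in_set[order]
    w = np.where(in_ord, ranks[order] ** tau, 0.0)
    p_in = np.cumsum(w) / w.sum()
    n_out = (~in_set).sum()
    p_out = np.cumsum(~in_ord) / n_out
    return float(np.sum(p_in - p_out))


def rescale_scores(raw, invert: bool = False) -> np.ndarray:
    """Min-max rescale a cohort's raw scores to [-1, 1], optionally inverted.

    A constant input has no dynamic range; it maps to all zeros with a
    warning rather than dividing by zero.
    """
    x = np.asarray(raw, dtype=float)
    if x.size < 2:
        raise ValueError("rescaling requires at least 2 samples")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant score vector rescaled to all zeros", stacklevel=2)
        out = np.zeros_like(x)
    else:
        out = 2.0 * (x - lo) / (hi - lo) - 1.0
    return -out if invert else out


def aggregate_activity(rescaled_spop_up, rescaled_erg_up_inverted) -> np.ndarray:
    """Elementwise mean of the two rescaled component scores (in [-1, 1])."""
    a = np.asarray(rescaled_spop_up, dtype=float)
    b = np.asarray(rescaled_erg_up_inverted, dtype=float)
    if a.shape != b.shape:
        raise ValueError("component score vectors cover different samples")
    return (a + b) / 2.0


def score_cohort(
    expr: ExpressionMatrix,
    signatures: SignatureSet,
    spop_set: str = "SPOP_up",
    erg_set: str = "ERG_up",
    tau: float = DEFAULT_TAU,
) -> pd.DataFrame:
    """Per-sample raw, rescaled and aggregate SPOP/ERG activity scores.

    The SPOP-up score is rescaled to [-1, 1]; the ERG-up score is rescaled
    and inverted (so that +1 always reads "SPOP-mutant-like"); the aggregate
    activity is their mean. Returns a samples x columns frame with the
    sample group labels attached.
    """
    for name in (spop_set, erg_set):
        if name not in signatures:
            raise KeyError(f"signature {name!r} not found")
    gene_ids = expr.gene_ids
    mat = expr.values.to_numpy()
    masks = {
        name: np.isin(gene_ids, list(signatures[name].genes))
        for name in (spop_set, erg_set)
    }
    for name, mask in masks.items():
        m = int(mask.sum())
        if m == 0 or m == len(gene_ids):
            raise ValueError(f"signature {name!r} is empty or covers all genes")
    raw = {name: np.empty(mat.shape[1]) for name in masks}
    for j in range(mat.shape[1]):
        ranks, order = _ranks_and_order(mat[:, j])
        for name, mask in masks.items():
            raw[name][j] = _es_from_ranks(ranks, order, mask, tau)
    spop_rescaled = rescale_scores(raw[spop_set], invert=False)
    erg_rescaled = rescale_scores(raw[erg_set], invert=True)
    return pd.DataFrame(
        {
            f"raw_{spop_set}": raw[spop_set],
            f"raw_{erg_set}": raw[erg_set],
            f"rescaled_{spop_set}": spop_rescaled,
            f"rescaled_{erg_set}_inverted": erg_rescaled,
            "aggregate": aggregate_activity(spop_rescaled, erg_rescaled),
            "group": expr.groups.to_numpy(),
        },
        index=pd.Index(expr.samples, name="sample"),
    )


def fisher_margin_pvalues(N: int, K: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher exact p for every 2x2 table with fixed margins.

    Margins: grand total ``N``, first-column total ``K``, first-row total
    ``n``. Returns the support of the top-left cell and, for each value,
    the sum of hypergeometric point probabilities not exceeding the
    observed one (with the conventional ``1 + 1e-7`` relative fuzz for
    floating-point ties). Vectorized over the whole support so that
    margin-grouped sweeps are cheap.
    """
    lo, hi = max(0, n - (N - K)), min(K, n)
    support = np.arange(lo, hi + 1)
    pmf = _stats.hypergeom.pmf(support, N, K, n)
    order = np.argsort(pmf, kind="stable")
    csum = np.cumsum(pmf[order])
    # for each observed pmf, include every table at most (1+1e-7)x as likely
    idx = np.searchsorted(pmf[order], pmf * (1 + 1e-7), side="right")
    p = np.minimum(csum[idx - 1], 1.0)
    return support, p


def fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for one 2x2 table ``[[a, b], [c, d]]``.

    Agrees with ``scipy.stats.fisher_exact(..., 'two-sided')``.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("table cells must be non-negative")
    support, p = fisher_margin_pvalues(a + b + c + d, a + c, a + b)
    return float(p[np.searchsorted(support, a)])


def camera_preranked(
    stats: pd.Series,
    signature_genes,
    rho: float = DEFAULT_RHO,
) -> EnrichmentResult:
    """Competitive pre-ranked gene-set test with inter-gene correlation.

    Compares the mean ranking statistic of the m in-set genes against the
    rest. The in-set mean's variance is inflated by ``VIF = 1 + (m-1)*rho``
    to account for positive correlation among co-regulated genes:

        t = delta / (s * sqrt(VIF/m + 1/(N-m))),  df = N - 2

    with ``delta`` the in/out mean difference and ``s**2`` the pooled
    two-group variance. At ``rho = 0`` this is exactly the pooled two-sample
    t-test. Two-sided p; direction reported separately as sign(delta).
    """
    if not (0 <= rho < 1):
        raise ValueError("rho must lie in [0, 1)")
    x = stats.to_numpy(dtype=float)
    n = x.size
    in_set = np.isin(stats.index.to_numpy(), list(signature_genes))
    m = int(in_set.sum())
    if m < 2 or n - m < 2:
        raise ValueError("need at least 2 genes inside and outside the set")
    delta = x[in_set].mean() - x[~in_set].mean()
    s2 = (
        (m - 1) * x[in_set].var(ddof=1) + (n - m - 1) * x[~in_set].var(ddof=1)
    ) / (n - 2)
    if s2 <= 0:
        raise ValueError("degenerate variance")
    vif = 1.0 + (m - 1) * rho
    t = delta / np.sqrt(s2 * (vif / m + 1.0 / (n - m)))
    p = float(2.0 * _stats.t.sf(abs(t), df=n - 2))
    return EnrichmentResult(
        name="", effect=float(delta), pvalue=p, fdr=None,
        direction=int(np.sign(delta)), n_set=m,
    )


def camera_enrich(
    de_stats: pd.Series,
    signatures: SignatureSet,
    rho: float = DEFAULT_RHO,
) -> pd.DataFrame:
    """Run camera_preranked over a signature collection with BH correction.

    Signatures too small (or too large) to test are skipped with a warning.
    """
    rows = []
    for name, sig in signatures.items():
        try:
            res = camera_preranked(de_stats, sig.genes, rho)
        except ValueError as exc:
            warnings.warn(f"skipping {name}: {exc}", stacklevel=2)
            continue
        rows.append((name, res.effect, res.direction, res.n_set, res.pvalue))
    frame = pd.DataFrame(
        rows, columns=["signature", "effect", "direction", "n_set", "pvalue"]
    ).set_index("signature")
    if len(frame):
        frame["fdr"] = bh_adjust(frame["pvalue"].to_numpy())
    else:
        frame["fdr"] = []
    return frame


def locus_enrichment(
    peaks: PeakSet,
    genes: GeneModel,
    signature_genes,
    half_width: int = LOCUS_HALF_WIDTH,
    name: str = "",
) -> EnrichmentResult:
    """Peak enrichment at signature-gene loci (TSS +/- half_width).

    A gene is "bound" iff at least one peak overlaps its locus window. The
    in-set x bound 2x2 table is tested with a two-sided Fisher exact test;
    the odds ratio uses a +0.5 Haldane-Anscombe correction when any cell is
    zero.
    """
    sig = set(signature_genes)
    if not sig:
        raise ValueError("empty signature")
    universe = set(genes.gene_ids)
    stray = sig - universe
    if stray:
        raise ValueError(f"signature genes absent from gene model: {sorted(stray)[:5]}")
    trees: dict[str, IntervalTree] = {}
    for chrom, ivs in peaks.by_chrom().items():
        trees[chrom] = IntervalTree.from_tuples((iv.start, iv.end) for iv in ivs)
    a = b = c = d = 0  # in&bound, in&unbound, out&bound, out&unbound
    for gene_id, rec in genes.frame.iterrows():
        w = locus_window(rec["chrom"], int(rec["tss"]), half_width)
        tree = trees.get(w.chrom)
        bound = bool(tree is not None and tree.overlap(w.start, w.end))
        if gene_id in sig:
            a, b = (a + 1, b) if bound else (a, b + 1)
        else:
            c, d = (c + 1, d) if bound else (c, d + 1)
    p = fisher_two_sided_p(a, b, c, d)
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return EnrichmentResult(
        name=name, effect=float(orr), pvalue=float(p), fdr=None,
        direction=int(np.sign(np.log(orr))) if orr != 1 else 0, n_set=a + b,
    )


def locus_enrich_collection(
    peaks: PeakSet,
    genes: GeneModel,
    signatures: SignatureSet,
    half_width: int = LOCUS_HALF_WIDTH,
) -> pd.DataFrame:
    """Locus enrichment of every signature in a collection, BH-corrected."""
    rows = []
    for name, sig in signatures.items():
        if not sig.genes:
            warnings.warn(f"skipping empty signature {name}", stacklevel=2)
            continue
        res = locus_enrichment(peaks, genes, sig.genes, half_width, name=name)
        rows.append((name, res.effect, res.direction, res.n_set, res.pvalue))
    frame = pd.DataFrame(
        rows, columns=["signature", "odds_ratio", "direction", "n_set", "pvalue"]
    ).set_index("signature")
    if len(frame):
        frame["fdr"] = bh_adjust(frame["pvalue"].to_numpy())
    else:
        frame["fdr"] = []
    return frame
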