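"""Synthetic inputs with planted truth for every pipeline stage.

The generators emulate the statistical structure of the real inputs the
pipeline was designed for — promoter-localized ChIP peaks with controlled
AR/ERG co-occupancy, signed differential-expression effects observed through
Gaussian noise on the log2 scale, two-group expression cohorts with planted
subtype signatures, and paired protein/mRNA fold changes with planted
discordant (stabilized-substrate-like) genes. Every generator is
deterministic under the global seed; one seed fans out to per-generator
substreams through fixed offsets so any single stage can be reproduced in
isolation.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotate import (
    PROMOTER_DOWNSTREAM,
    PROMOTER_UPSTREAM,
    BindingClass,
    promoter_window,
)
from .signatures import bh_adjust
from .types import (
    DifferentialTable,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    PeakSet,
    ProteomeTable,
    SignatureSet,
)

# fixed substream offsets: reproducing stage k needs only (seed, offset_k)
_STREAM = {
    "gene_model": 11,
    "classes": 12,
    "cistrome": 13,
    "de_dht": 14,
    "de_erg_kd": 15,
    "subtype_genes": 16,
    "de_subtype": 17,
    "expression": 18,
    "proteome": 19,
}

DEFAULT_CLASS_FRACTIONS = {
    BindingClass.NONE: 0.60,
    BindingClass.AR_ONLY: 0.15,
    BindingClass.ERG_ONLY: 0.15,
    BindingClass.CO_BOUND: 0.06,
    BindingClass.BOTH_DISJOINT: 0.04,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults: a 5000-gene genome on 5 toy chromosomes; TF peaks ~300 bp;
    perturbation contrasts with log2 effect 2 observed at s.e. 0.25; a
    20+20-sample two-subtype cohort with expression shift 1.0 against noise
    s.d. 0.5; subtype signatures of 443 (SPOP-up) and 359 (ERG-up) genes;
    and a 1000-protein proteome with 50 planted discordant substrates
    (protein effect 1.0, noise s.d. 0.15).
    """

    n_genes: int = 5000
    n_chroms: int = 5
    class_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    peak_width_mean: float = 300.0
    peak_width_sd: float = 50.0
    de_effect_log2fc: float = 2.0
    de_se: float = 0.25
    null_response_fraction: float = 0.1
    n_samples_per_group: int = 20
    expr_effect: float = 1.0
    expr_noise_sd: float = 0.5
    n_spop_up: int = 443
    n_erg_up: int = 359
    subtype_effect: float = 2.0
    subtype_se: float = 0.25
    n_proteins: int = 1000
    n_substrates: int = 50
    substrate_effect: float = 1.0
    substrate_noise_sd: float = 0.15
    low_peptide_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        for name in ("de_se", "expr_noise_sd", "subtype_se", "substrate_noise_sd",
                     "peak_width_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAM[stream]])


@dataclass
class SimTruth:
    """Planted ground truth accumulated across generators."""

    genes: pd.DataFrame  # class, dht_dir, ergkd_dir per gene
    expected_signatures: dict[str, list[str]] = field(default_factory=dict)
    spop_up: list[str] = field(default_factory=list)
    erg_up: list[str] = field(default_factory=list)
    sample_groups: dict[str, str] = field(default_factory=dict)
    proteome: pd.DataFrame | None = None  # substrate / concordant flags


def simulate_gene_model(config: SimConfig) -> GeneModel:
    """Place genes on toy chromosomes with >=10 kb spacing.

    The spacing guarantees promoter windows never overlap, so planted
    binding classes are unambiguous.
    """
    rng = config.rng("gene_model")
    per_chrom = np.array_split(np.arange(config.n_genes), config.n_chroms)
    records = []
    width = len(str(config.n_genes))
    for ci, idx in enumerate(per_chrom, start=1):
        gaps = 10_000 + rng.integers(0, 10_000, size=len(idx))
        tss = 20_000 + np.cumsum(gaps)
        strands = rng.choice(["+", "-"], size=len(idx))
        for g, t, s in zip(idx, tss, strands):
            gid = f"g{g + 1:0{width}d}"
            records.append((gid, f"GENE{g + 1}", f"chr{ci}", s, int(t)))
    frame = pd.DataFrame(
        records, columns=["gene_id", "symbol", "chrom", "strand", "tss"]
    )
    return GeneModel(frame)


def _assign_classes(config: SimConfig, gene_ids: list[str]) -> pd.Series:
    """Largest-remainder class counts, then a seeded shuffle."""
    n = len(gene_ids)
    items = sorted(config.class_fractions.items(), key=lambda kv: str(kv[0]))
    raw = {c: f * n for c, f in items}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    for c, _ in sorted(raw.items(), key=lambda kv: -(kv[1] - np.floor(kv[1]))):
        if short == 0:
            break
        counts[c] += 1
        short -= 1
    labels = np.concatenate(
        [np.repeat(str(BindingClass(c).value), k) for c, k in counts.items()]
    )
    rng = config.rng("classes")
    rng.shuffle(labels)
    return pd.Series(labels, index=gene_ids, name="class")


def _plant_directions(
    config: SimConfig, classes: pd.Series, rng: np.random.Generator
) -> pd.DataFrame:
    """Plant signed responses per gene for the DHT and ERG-silencing contrasts.

    Bound classes respond deterministically in planted directions (split
    half/half for the two "only" classes); a fraction of unbound genes
    responds too, modelling indirect targets that must not leak into the
    binding-gated signatures.
    """
    frame = pd.DataFrame(
        {"class": classes, "dht_dir": 0, "ergkd_dir": 0}, index=classes.index
    )
    for cls, col in ((BindingClass.AR_ONLY, "dht_dir"),
                     (BindingClass.ERG_ONLY, "ergkd_dir")):
        ids = frame.index[frame["class"] == cls.value]
        signs = np.where(np.arange(len(ids)) % 2 == 0, 1, -1)
        frame.loc[ids, col] = rng.permutation(signs)
    both = frame["class"].isin(
        [BindingClass.CO_BOUND.value, BindingClass.BOTH_DISJOINT.value]
    )
    frame.loc[both, ["dht_dir", "ergkd_dir"]] = 1
    none_ids = frame.index[frame["class"] == BindingClass.NONE.value]
    for col in ("dht_dir", "ergkd_dir"):
        hit = rng.random(len(none_ids)) < config.null_response_fraction
        signs = rng.choice([-1, 1], size=len(none_ids))
        frame.loc[none_ids[hit], col] = signs[hit]
    return frame


def expected_signatures(truth_frame: pd.DataFrame) -> dict[str, list[str]]:
    """Apply the signature set algebra to the *planted* directions.

    This is the noise-free membership the builder should recover when the
    observed contrasts have enough power. Sign convention: an ERG-induced
    gene has ``ergkd_dir = -1`` (down upon silencing).
    """
    cls = truth_frame["class"]
    dht = truth_frame["dht_dir"]
    erg = truth_frame["ergkd_dir"]
    ar_only = cls == BindingClass.AR_ONLY.value
    erg_only = cls == BindingClass.ERG_ONLY.value
    co = cls == BindingClass.CO_BOUND.value
    out = {
        "DHT_induced": ar_only & (dht > 0) & ~(erg < 0),
        "DHT_repressed": ar_only & (dht < 0) & ~(erg > 0),
        "ERG_induced": erg_only & (erg < 0) & ~(dht > 0),
        "ERG_repressed": erg_only & (erg > 0) & ~(dht < 0),
        "CoBound_DHTind_ERGrep": co & (dht > 0) & (erg > 0),
    }
    return {k: truth_frame.index[v].tolist() for k, v in out.items()}


def simulate_cistrome(
    genes: GeneModel, config: SimConfig
) -> tuple[PeakSet, PeakSet, SimTruth]:
    """Place AR/ERG peaks inside promoters to realize planted classes exactly.

    CO_BOUND genes receive a mutually overlapping AR/ERG peak pair;
    BOTH_DISJOINT genes receive promoter-resident but disjoint peaks
    separated by at least one base. Classifying the output reproduces the
    planted classes with 100% agreement.
    """
    prom_len = PROMOTER_UPSTREAM + PROMOTER_DOWNSTREAM
    max_w = prom_len // 2 - 1
    if config.peak_width_mean > max_w:
        raise ValueError(
            f"peak width {config.peak_width_mean} cannot realize paired "
            f"classes inside a {prom_len} bp promoter"
        )
    classes = _assign_classes(config, genes.gene_ids)
    rng = config.rng("cistrome")
    truth_frame = _plant_directions(config, classes, rng)

    def draw_width() -> int:
        w = rng.normal(config.peak_width_mean, config.peak_width_sd)
        return int(np.clip(round(w), 20, max_w))

    ar_peaks: list[GenomicInterval] = []
    erg_peaks: list[GenomicInterval] = []
    for gene_id, rec in genes.frame.iterrows():
        cls = BindingClass(classes.loc[gene_id])
        if cls is BindingClass.NONE:
            continue
        prom = promoter_window(rec["chrom"], rec["strand"], int(rec["tss"]))
        if cls is BindingClass.AR_ONLY or cls is BindingClass.ERG_ONLY:
            w = draw_width()
            start = int(rng.integers(prom.start, prom.end - w + 1))
            peak = GenomicInterval(prom.chrom, start, start + w)
            (ar_peaks if cls is BindingClass.AR_ONLY else erg_peaks).append(peak)
        else:
            wa, we = draw_width(), draw_width()
            if cls is BindingClass.CO_BOUND:
                sa = int(rng.integers(prom.start, prom.end - wa - we + 1))
                ov = int(rng.integers(1, min(wa, we) + 1))
                se_ = sa + wa - ov
            else:  # BOTH_DISJOINT: gap of >=1 bp between the peaks
                slack = (prom.end - prom.start) - wa - we - 1
                sa = prom.start + int(rng.integers(0, slack))
                gap = 1 + int(rng.integers(0, prom.end - (sa + wa + we) - 1 + 1))
                se_ = sa + wa + gap
            ar_peaks.append(GenomicInterval(prom.chrom, sa, sa + wa))
            erg_peaks.append(GenomicInterval(prom.chrom, se_, se_ + we))

    truth = SimTruth(genes=truth_frame)
    truth.expected_signatures = expected_signatures(truth_frame)
    return PeakSet("AR", ar_peaks), PeakSet("ERG", erg_peaks), truth


def _de_from_directions(
    dirs: pd.Series, effect: float, se: float, rng: np.random.Generator
) -> DifferentialTable:
    log2fc = dirs.to_numpy(dtype=float) * effect + rng.normal(0, se, len(dirs))
    stat = log2fc / se
    pvalue = 2.0 * _norm_sf(np.abs(stat))
    frame = pd.DataFrame(
        {
            "log2fc": log2fc,
            "stat": stat,
            "pvalue": pvalue,
            "fdr": bh_adjust(pvalue),
        },
        index=pd.Index(dirs.index, name="gene_id"),
    )
    return DifferentialTable(frame)


def _norm_sf(x: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.sf(x)


def simulate_de_table(
    truth: SimTruth, contrast: str, config: SimConfig
) -> DifferentialTable:
    """Observed DE table for one perturbation contrast.

    ``log2fc ~ Normal(dir * effect, se)``, ``stat = log2fc / se`` (a Wald
    statistic), two-sided normal p, BH FDR.
    """
    if contrast == "dht":
        dirs, stream = truth.genes["dht_dir"], "de_dht"
    elif contrast == "erg_kd":
        dirs, stream = truth.genes["ergkd_dir"], "de_erg_kd"
    else:
        raise ValueError("contrast must be 'dht' or 'erg_kd'")
    return _de_from_directions(
        dirs, config.de_effect_log2fc, config.de_se, config.rng(stream)
    )


def pick_subtype_genes(
    genes: GeneModel, config: SimConfig
) -> tuple[list[str], list[str]]:
    """Disjoint planted SPOP-up and ERG-up subtype gene lists."""
    n = config.n_spop_up + config.n_erg_up
    if n > len(genes):
        raise ValueError("subtype signatures larger than the gene universe")
    rng = config.rng("subtype_genes")
    chosen = rng.choice(len(genes), size=n, replace=False)
    ids = np.asarray(genes.gene_ids)
    return (
        sorted(ids[chosen[: config.n_spop_up]]),
        sorted(ids[chosen[config.n_spop_up:]]),
    )


def simulate_subtype_de(
    genes: GeneModel,
    spop_up: list[str],
    erg_up: list[str],
    config: SimConfig,
) -> DifferentialTable:
    """Observed SPOP-mutant vs ERG-fused contrast with planted subtype effects."""
    dirs = pd.Series(0, index=pd.Index(genes.gene_ids, name="gene_id"))
    dirs.loc[spop_up] = 1
    dirs.loc[erg_up] = -1
    return _de_from_directions(
        dirs, config.subtype_effect, config.subtype_se, config.rng("de_subtype")
    )


def simulate_expression(
    genes: GeneModel,
    spop_up: list[str],
    erg_up: list[str],
    config: SimConfig,
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Two-group cohort with mirrored planted subtype signatures.

    SPOP-like samples shift ``spop_up`` genes up and ``erg_up`` genes down
    by ``expr_effect`` (ERG-like samples mirrored) over a common per-gene
    baseline plus Gaussian noise.
    """
    if set(spop_up) & set(erg_up):
        raise ValueError("subtype signatures must be disjoint")
    rng = config.rng("expression")
    ids = genes.gene_ids
    n_g, n_s = len(ids), 2 * config.n_samples_per_group
    baseline = rng.normal(8.0, 2.0, size=n_g)
    shift = np.zeros(n_g)
    idx = {g: i for i, g in enumerate(ids)}
    shift[[idx[g] for g in spop_up]] = config.expr_effect
    shift[[idx[g] for g in erg_up]] = -config.expr_effect
    group_sign = np.array(
        [1] * config.n_samples_per_group + [-1] * config.n_samples_per_group
    )
    mat = (
        baseline[:, None]
        + shift[:, None] * group_sign[None, :]
        + rng.normal(0, config.expr_noise_sd, size=(n_g, n_s))
    )
    samples = [f"SPOP_{i + 1:02d}" for i in range(config.n_samples_per_group)] + [
        f"ERG_{i + 1:02d}" for i in range(config.n_samples_per_group)
    ]
    groups = {
        s: ("SPOP-like" if i < config.n_samples_per_group else "ERG-like")
        for i, s in enumerate(samples)
    }
    values = pd.DataFrame(mat, index=pd.Index(ids, name="gene_id"), columns=samples)
    return ExpressionMatrix(values, groups), groups


PROTEOME_CONDITIONS = ("SPOP_Y87C", "SPOP_F102C", "SPOP_W131G")


def simulate_proteome(
    genes: GeneModel, config: SimConfig
) -> tuple[ProteomeTable, DifferentialTable, pd.DataFrame]:
    """Paired protein/mRNA fold changes with planted discordance.

    Planted substrates: protein effect ``substrate_effect`` in every mutant
    condition, mRNA effect 0. A matched concordant set gets the same effect
    in both layers (transcriptionally driven, must be rejected). The rest is
    null. Peptide counts include a planted low-evidence fraction (<2 unique
    peptides) among null proteins to exercise the hygiene filter.
    """
    if config.n_substrates * 2 > config.n_proteins:
        raise ValueError("too many planted genes for the proteome size")
    if config.n_proteins > len(genes):
        raise ValueError("n_proteins exceeds the gene universe")
    rng = config.rng("proteome")
    ids = np.asarray(genes.gene_ids)[
        rng.choice(len(genes), size=config.n_proteins, replace=False)
    ]
    role = np.array(["null"] * config.n_proteins, dtype=object)
    role[: config.n_substrates] = "substrate"
    role[config.n_substrates: 2 * config.n_substrates] = "concordant"
    rng.shuffle(role)

    prot_effect = np.where(role == "null", 0.0, config.substrate_effect)
    rna_effect = np.where(role == "concordant", config.substrate_effect, 0.0)
    sd = config.substrate_noise_sd
    data = {"gene_id": ids}
    for cond in PROTEOME_CONDITIONS:
        data[cond] = prot_effect + rng.normal(0, sd, config.n_proteins)
    peptides = 2 + rng.poisson(3.0, config.n_proteins)
    low = (role == "null") & (rng.random(config.n_proteins)
                              < config.low_peptide_fraction)
    peptides[low] = 1
    frame = pd.DataFrame(data)
    frame["n_unique_peptides"] = peptides
    prot = ProteomeTable(frame, list(PROTEOME_CONDITIONS))

    rna = _de_from_directions(
        pd.Series(rna_effect / max(config.substrate_effect, 1e-12),
                  index=pd.Index(ids, name="gene_id")),
        config.substrate_effect,
        sd,
        rng,
    )
    truth = pd.DataFrame(
        {"role": role, "substrate": role == "substrate"},
        index=pd.Index(ids, name="gene_id"),
    )
    return prot, rna, truth


@dataclass
class SimBundle:
    """Everything one seeded run of the generator produces."""

    config: SimConfig
    genes: GeneModel
    ar: PeakSet
    erg: PeakSet
    de_dht: DifferentialTable
    de_erg_kd: DifferentialTable
    de_subtype: DifferentialTable
    expression: ExpressionMatrix
    proteome: ProteomeTable
    proteome_rna: DifferentialTable
    truth: SimTruth


def simulate_all(config: SimConfig) -> SimBundle:
    """Run every generator under one seed and assemble the planted truth."""
    genes = simulate_gene_model(config)
    ar, erg, truth = simulate_cistrome(genes, config)
    de_dht = simulate_de_table(truth, "dht", config)
    de_erg_kd = simulate_de_table(truth, "erg_kd", config)
    spop_up, erg_up = pick_subtype_genes(genes, config)
    truth.spop_up, truth.erg_up = spop_up, erg_up
    de_subtype = simulate_subtype_de(genes, spop_up, erg_up, config)
    expression, groups = simulate_expression(genes, spop_up, erg_up, config)
    truth.sample_groups = groups
    proteome, proteome_rna, prot_truth = simulate_proteome(genes, config)
    truth.proteome = prot_truth
    return SimBundle(
        config=config, genes=genes, ar=ar, erg=erg, de_dht=de_dht,
        de_erg_kd=de_erg_kd, de_subtype=de_subtype, expression=expression,
        proteome=proteome, proteome_rna=proteome_rna, truth=truth,
    )


def truth_signature_set(truth: SimTruth) -> SignatureSet:
    """Planted signature membership as a SignatureSet (for GMT export)."""
    sigs = SignatureSet()
    for name, members in truth.expected_signatures.items():
        sigs.add(name, members, "planted truth")
    if truth.spop_up:
        sigs.add("SPOP_up", truth.spop_up, "planted truth")
    if truth.erg_up:
        sigs.add("ERG_up", truth.erg_up, "planted truth")
    return sigs


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """A copy of ``config`` under a different seed."""
    return replace(config, seed=int(seed))
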