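"""End-to-end orchestration: simulate -> classify -> signatures -> score ->
enrich -> substrates, with a provenance manifest.

Every stage reads and writes plain-text files through :mod:`cistromesig.io`,
so each is runnable standalone on files produced by any conforming tool.
Runs are fully deterministic under a fixed config and seed; the manifest
records parameters, per-output SHA-256 checksums and row counts (and no
timestamps, so identical runs yield identical manifests).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from importlib import metadata

from . import io as csio
from .annotate import LOCUS_HALF_WIDTH, classify_genes, merge_peak_sets
from .scoring import (
    DEFAULT_RHO,
    DEFAULT_TAU,
    camera_enrich,
    locus_enrich_collection,
    score_cohort,
)
from .signatures import (
    SignatureRuleParams,
    build_ar_erg_signatures,
    build_subtype_signatures,
)
from .simulate import SimConfig, simulate_all, truth_signature_set
from .substrates import (
    calls_to_frame,
    filter_min_peptides,
    median_normalize,
    nominate_substrates,
)

log = logging.getLogger("cistromesig")

ALL_STAGES = (
    "simulate",
    "classify",
    "signatures",
    "subtype_sig",
    "score",
    "enrich",
    "locus_enrich",
    "substrates",
)


class PipelineError(RuntimeError):
    """A stage could not run (missing upstream artifact or bad config)."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed for one pipeline run."""

    outdir: str = "pipeline_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    fdr_threshold: float = 0.05
    subtype_log2fc_threshold: float = 1.0
    tau: float = DEFAULT_TAU
    rho: float = DEFAULT_RHO
    locus_half_width: int = LOCUS_HALF_WIDTH
    min_peptides: int = 2
    prot_lfc_thr: float = 0.5
    rna_lfc_cap: float = 0.25
    rna_fdr_floor: float = 0.05
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise PipelineError(f"unknown stages: {unknown}")
        self.sim = dataclasses.replace(self.sim, seed=int(self.seed))

    @classmethod
    def from_toml(cls, path: str, **overrides) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim_raw = raw.pop("simulate", {})
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        sim = SimConfig(**sim_raw) if sim_raw else SimConfig()
        return cls(sim=sim, **raw)

    def path(self, name: str) -> str:
        return os.path.join(self.outdir, name)


def _require(cfg: PipelineConfig, stage: str, *names: str) -> list[str]:
    paths = [cfg.path(n) for n in names]
    for p in paths:
        if not os.path.exists(p):
            raise PipelineError(f"stage {stage!r}: missing input {p}")
    return paths


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _count_rows(path: str) -> int:
    with open(path) as fh:
        return max(0, sum(1 for _ in fh) - (0 if path.endswith(".bed") else 1))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    os.makedirs(cfg.outdir, exist_ok=True)
    params = SignatureRuleParams(cfg.fdr_threshold, cfg.subtype_log2fc_threshold)
    manifest: dict = {
        "package": "cistromesig",
        "version": _version(),
        "seed": int(cfg.seed),
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(cfg).items()
            if k not in ("outdir", "stages", "sim")
        },
        "sim": {k: _jsonable(v) for k, v in dataclasses.asdict(cfg.sim).items()},
        "stages": [],
    }

    def record(stage: str, outputs: list[str]) -> None:
        entry = {
            "name": stage,
            "outputs": {
                os.path.basename(p): {"sha256": _sha256(p), "rows": _count_rows(p)}
                for p in outputs
            },
        }
        manifest["stages"].append(entry)

    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        outputs = _STAGE_FUNCS[stage](cfg, params)
        total = sum(_count_rows(p) for p in outputs)
        log.info("stage=%s n_outputs=%d n_rows=%d", stage, len(outputs), total)
        record(stage, outputs)

    manifest_path = cfg.path("manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _version() -> str:
    try:
        return metadata.version("cistromesig")
    except metadata.PackageNotFoundError:
        return "unknown"


def _jsonable(v):
    if isinstance(v, dict):
        return {str(k): _jsonable(x) for k, x in v.items()}
    return v


def _stage_simulate(cfg: PipelineConfig, params) -> list[str]:
    bundle = simulate_all(cfg.sim)
    p = cfg.path
    csio.write_gene_model(bundle.genes, p("genes.tsv"))
    csio.write_bed(bundle.ar, p("ar.bed"))
    csio.write_bed(bundle.erg, p("erg.bed"))
    csio.write_de_table(bundle.de_dht, p("de_dht.tsv"))
    csio.write_de_table(bundle.de_erg_kd, p("de_ergkd.tsv"))
    csio.write_de_table(bundle.de_subtype, p("de_subtype.tsv"))
    csio.write_expression(bundle.expression, p("expr.tsv"), p("groups.tsv"))
    csio.write_proteome(bundle.proteome, p("prot.tsv"))
    csio.write_de_table(bundle.proteome_rna, p("prot_rna.tsv"))
    csio.write_classes(
        dict(bundle.truth.genes["class"]), p("truth_classes.tsv")
    )
    csio.write_gmt(truth_signature_set(bundle.truth), p("truth_signatures.gmt"))
    return [
        p(n)
        for n in (
            "genes.tsv", "ar.bed", "erg.bed", "de_dht.tsv", "de_ergkd.tsv",
            "de_subtype.tsv", "expr.tsv", "groups.tsv", "prot.tsv",
            "prot_rna.tsv", "truth_classes.tsv", "truth_signatures.gmt",
        )
    ]


def _stage_classify(cfg: PipelineConfig, params) -> list[str]:
    genes_p, ar_p, erg_p = _require(cfg, "classify", "genes.tsv", "ar.bed", "erg.bed")
    genes = csio.read_gene_model(genes_p)
    ar = csio.read_bed(ar_p, factor="AR")
    erg = csio.read_bed(erg_p, factor="ERG")
    ar = merge_peak_sets(ar, ar)  # coalesce any overlapping inputs
    erg = merge_peak_sets(erg, erg)
    classes = classify_genes(genes, ar, erg)
    out = cfg.path("classes.tsv")
    csio.write_classes({g: str(c) for g, c in classes.items()}, out)
    return [out]


def _stage_signatures(cfg: PipelineConfig, params) -> list[str]:
    classes_p, dht_p, erg_p = _require(
        cfg, "signatures", "classes.tsv", "de_dht.tsv", "de_ergkd.tsv"
    )
    from .annotate import BindingClass

    classes = {g: BindingClass(c) for g, c in csio.read_classes(classes_p).items()}
    sigs = build_ar_erg_signatures(
        classes, csio.read_de_table(dht_p), csio.read_de_table(erg_p), params
    )
    out = cfg.path("signatures.gmt")
    csio.write_gmt(sigs, out)
    return [out]


def _stage_subtype(cfg: PipelineConfig, params) -> list[str]:
    (subtype_p,) = _require(cfg, "subtype_sig", "de_subtype.tsv")
    sigs = build_subtype_signatures(csio.read_de_table(subtype_p), params)
    out = cfg.path("subtype.gmt")
    csio.write_gmt(sigs, out)
    return [out]


def _stage_score(cfg: PipelineConfig, params) -> list[str]:
    expr_p, groups_p, gmt_p = _require(
        cfg, "score", "expr.tsv", "groups.tsv", "subtype.gmt"
    )
    expr = csio.read_expression(expr_p, groups_p)
    sigs = csio.read_gmt(gmt_p)
    if "SPOP_up" not in sigs or "ERG_up" not in sigs:
        raise PipelineError("stage 'score': signatures required (SPOP_up/ERG_up)")
    table = score_cohort(expr, sigs, tau=cfg.tau)
    out = cfg.path("scores.tsv")
    table.to_csv(out, sep="\t", float_format=csio.FLOAT_FMT)
    return [out]


def _stage_enrich(cfg: PipelineConfig, params) -> list[str]:
    subtype_p, gmt_p, sub_gmt_p = _require(
        cfg, "enrich", "de_subtype.tsv", "signatures.gmt", "subtype.gmt"
    )
    de = csio.read_de_table(subtype_p)
    sigs = csio.read_gmt(gmt_p)
    for name, sig in csio.read_gmt(sub_gmt_p).items():
        sigs.add(name, sig.genes, sig.provenance)
    table = camera_enrich(de.frame["stat"], sigs, rho=cfg.rho)
    out = cfg.path("enrichment.tsv")
    table.to_csv(out, sep="\t", float_format=csio.FLOAT_FMT)
    return [out]


def _stage_locus_enrich(cfg: PipelineConfig, params) -> list[str]:
    ar_p, genes_p, gmt_p = _require(
        cfg, "locus_enrich", "ar.bed", "genes.tsv", "signatures.gmt"
    )
    peaks = csio.read_bed(ar_p, factor="AR")
    genes = csio.read_gene_model(genes_p)
    sigs = csio.read_gmt(gmt_p)
    table = locus_enrich_collection(peaks, genes, sigs, cfg.locus_half_width)
    out = cfg.path("locus_enrichment.tsv")
    table.to_csv(out, sep="\t", float_format=csio.FLOAT_FMT)
    return [out]


def _stage_substrates(cfg: PipelineConfig, params) -> list[str]:
    prot_p, rna_p = _require(cfg, "substrates", "prot.tsv", "prot_rna.tsv")
    prot = median_normalize(
        filter_min_peptides(csio.read_proteome(prot_p), cfg.min_peptides)
    )
    calls = nominate_substrates(
        prot,
        csio.read_de_table(rna_p),
        prot_lfc_thr=cfg.prot_lfc_thr,
        rna_lfc_cap=cfg.rna_lfc_cap,
        rna_fdr_floor=cfg.rna_fdr_floor,
    )
    out = cfg.path("substrates.tsv")
    calls_to_frame(calls).to_csv(out, sep="\t", float_format=csio.FLOAT_FMT)
    return [out]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "signatures": _stage_signatures,
    "subtype_sig": _stage_subtype,
    "score": _stage_score,
    "enrich": _stage_enrich,
    "locus_enrich": _stage_locus_enrich,
    "substrates": _stage_substrates,
}
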