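"""Direction-aware AR/ERG signature construction with cross-exclusion rules.

Five binding-informed signatures are derived from the co-binding classes and
two differential contrasts (DHT treatment and ERG silencing), plus the pair
of subtype signatures (SPOP-up / ERG-up) derived from a clinical
SPOP-mutant vs ERG-fused contrast.

Sign conventions
----------------
- DHT contrast: ``log2fc > 0`` means induced by DHT.
- ERG-silencing contrast: a gene that goes *down* upon knockdown is
  ERG-induced; one that goes *up* is ERG-repressed.
- Subtype contrast: ``log2fc > 0`` means higher in SPOP-mutant tumors.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .annotate import BindingClass
from .types import DifferentialTable, SignatureSet

AR_ERG_SIGNATURE_NAMES = (
    "DHT_induced",
    "DHT_repressed",
    "ERG_induced",
    "ERG_repressed",
    "CoBound_DHTind_ERGrep",
)


@dataclass(frozen=True)
class SignatureRuleParams:
    """Thresholds governing signature membership.

    ``fdr_threshold`` gates significance in every contrast (strict ``<``);
    ``subtype_log2fc_threshold`` is the additional absolute-effect gate for
    the subtype signatures (strict ``>``). Ties at a threshold are excluded.
    """

    fdr_threshold: float = 0.05
    subtype_log2fc_threshold: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must be in (0, 1]")
        if self.subtype_log2fc_threshold <= 0:
            raise ValueError("subtype_log2fc_threshold must be positive")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    Permutation-equivariant: a permuted input yields identically permuted
    output.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return _stats.false_discovery_control(p, method="bh")


def significant_up(de: DifferentialTable, fdr_thr: float = 0.05) -> set[str]:
    """Genes significantly up in a contrast: ``fdr < fdr_thr`` and ``log2fc > 0``."""
    f = de.frame
    mask = (f["fdr"] < fdr_thr) & (f["log2fc"] > 0)
    return set(f.index[mask])


def significant_down(de: DifferentialTable, fdr_thr: float = 0.05) -> set[str]:
    """Genes significantly down in a contrast: ``fdr < fdr_thr`` and ``log2fc < 0``."""
    f = de.frame
    mask = (f["fdr"] < fdr_thr) & (f["log2fc"] < 0)
    return set(f.index[mask])


def _ordered(genes: set[str], order: list[str]) -> list[str]:
    pos = {g: i for i, g in enumerate(order)}
    return sorted(genes, key=lambda g: pos.get(g, len(pos)))


def build_ar_erg_signatures(
    classes: dict[str, BindingClass],
    de_dht: DifferentialTable,
    de_erg_kd: DifferentialTable,
    params: SignatureRuleParams = SignatureRuleParams(),
) -> SignatureSet:
    """Build the five binding-informed AR/ERG signatures.

    Set algebra (sigUp/sigDown at ``params.fdr_threshold``; genes absent from
    a contrast are treated as not significant):

    - DHT_induced  = AR_ONLY  & sigUp(dht)     - sigDown(erg_kd)
    - DHT_repressed = AR_ONLY & sigDown(dht)   - sigUp(erg_kd)
    - ERG_induced  = ERG_ONLY & sigDown(erg_kd) - sigUp(dht)
    - ERG_repressed = ERG_ONLY & sigUp(erg_kd) - sigDown(dht)
    - CoBound_DHTind_ERGrep = CO_BOUND & sigUp(dht) & sigUp(erg_kd)

    The cross-exclusions keep the four single-factor sets specific: a gene
    that responds to both perturbations cannot sit in an "only" signature.
    ``BOTH_DISJOINT`` and ``NONE`` genes appear in no signature. Gene order
    within each signature follows the classification map's order.
    """
    thr = params.fdr_threshold
    by_class: dict[BindingClass, set[str]] = {c: set() for c in BindingClass}
    for gene, cls in classes.items():
        by_class[BindingClass(cls)].add(gene)

    dht_up = significant_up(de_dht, thr)
    dht_down = significant_down(de_dht, thr)
    ergkd_up = significant_up(de_erg_kd, thr)
    ergkd_down = significant_down(de_erg_kd, thr)

    order = list(classes)
    sigs = SignatureSet()
    sigs.add(
        "DHT_induced",
        _ordered(by_class[BindingClass.AR_ONLY] & dht_up - ergkd_down, order),
        f"AR_ONLY promoter & DHT up (FDR<{thr}) minus ERG-induced "
        f"(down on ERG silencing, FDR<{thr})",
    )
    sigs.add(
        "DHT_repressed",
        _ordered(by_class[BindingClass.AR_ONLY] & dht_down - ergkd_up, order),
        f"AR_ONLY promoter & DHT down (FDR<{thr}) minus ERG-repressed "
        f"(up on ERG silencing, FDR<{thr})",
    )
    sigs.add(
        "ERG_induced",
        _ordered(by_class[BindingClass.ERG_ONLY] & ergkd_down - dht_up, order),
        f"ERG_ONLY promoter & down on ERG silencing (FDR<{thr}) minus "
        f"DHT-induced (FDR<{thr})",
    )
    sigs.add(
        "ERG_repressed",
        _ordered(by_class[BindingClass.ERG_ONLY] & ergkd_up - dht_down, order),
        f"ERG_ONLY promoter & up on ERG silencing (FDR<{thr}) minus "
        f"DHT-repressed (FDR<{thr})",
    )
    sigs.add(
        "CoBound_DHTind_ERGrep",
        _ordered(by_class[BindingClass.CO_BOUND] & dht_up & ergkd_up, order),
        f"CO_BOUND promoter (>=1 bp AR/ERG overlap) & DHT up & up on ERG "
        f"silencing (both FDR<{thr})",
    )
    return sigs


def build_subtype_signature(
    de_subtype: DifferentialTable,
    direction: str,
    params: SignatureRuleParams = SignatureRuleParams(),
) -> list[str]:
    """Subtype signature from a SPOP-mutant vs ERG-fused contrast.

    ``direction='up'`` (SPOP-up): ``log2fc > threshold`` and
    ``fdr < fdr_threshold``. ``direction='down'`` (ERG-up): the same rule on
    the opposite sign, ``log2fc < -threshold``. Output preserves table order.
    """
    f = de_subtype.frame
    lfc = params.subtype_log2fc_threshold
    if direction == "up":
        mask = (f["log2fc"] > lfc) & (f["fdr"] < params.fdr_threshold)
    elif direction == "down":
        mask = (f["log2fc"] < -lfc) & (f["fdr"] < params.fdr_threshold)
    else:
        raise ValueError("direction must be 'up' or 'down'")
    return list(f.index[mask])


def build_subtype_signatures(
    de_subtype: DifferentialTable,
    params: SignatureRuleParams = SignatureRuleParams(),
) -> SignatureSet:
    """Both subtype signatures (SPOP_up and ERG_up) as a SignatureSet."""
    sigs = SignatureSet()
    rule = (
        f"|log2FC|>{params.subtype_log2fc_threshold}, "
        f"FDR<{params.fdr_threshold} in SPOP-mutant vs ERG-fused contrast"
    )
    sigs.add("SPOP_up", build_subtype_signature(de_subtype, "up", params),
             f"higher in SPOP-mutant: {rule}")
    sigs.add("ERG_up", build_subtype_signature(de_subtype, "down", params),
             f"higher in ERG-fused: {rule}")
    return sigs
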