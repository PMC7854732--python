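"""Proteome-table hygiene and proteome-vs-transcriptome substrate nomination.

A stabilized ubiquitin-ligase substrate shows higher protein abundance in
mutant cells without a matching mRNA increase. After peptide-evidence
filtering and per-condition median normalization, a gene is nominated as a
candidate substrate when its mean protein log2FC across mutant conditions
clears a threshold while its mRNA is either non-significant or essentially
flat.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import DifferentialTable, ProteomeTable


@dataclass(frozen=True)
class SubstrateCall:
    gene_id: str
    mean_protein_log2fc: float
    rna_log2fc: float | None
    rna_fdr: float | None
    candidate: bool
    rule: str


def filter_min_peptides(table: ProteomeTable, k: int = 2) -> ProteomeTable:
    """Keep proteins identified by at least ``k`` unique peptides."""
    if k < 1:
        raise ValueError("k must be >= 1")
    kept = table.frame[table.frame["n_unique_peptides"] >= k]
    return ProteomeTable(kept.copy(), table.conditions)


def median_normalize(table: ProteomeTable) -> ProteomeTable:
    """Centre every condition column at zero by subtracting its median.

    Idempotent: a second application is a no-op.
    """
    if len(table) == 0:
        raise ValueError("cannot normalize an empty table")
    frame = table.frame.copy()
    for cond in table.conditions:
        frame[cond] = frame[cond] - frame[cond].median()
    return ProteomeTable(frame, table.conditions)


def drop_flagged(table: ProteomeTable, flag_column: str) -> ProteomeTable:
    """Remove rows with a truthy value in ``flag_column`` (e.g. contaminant
    or reversed-hit marks carried over from upstream search software)."""
    if flag_column not in table.frame.columns:
        raise ValueError(f"no column {flag_column!r} in proteome table")
    kept = table.frame[~table.frame[flag_column].astype(bool)]
    return ProteomeTable(kept.drop(columns=[flag_column]), table.conditions)


def nominate_substrates(
    prot: ProteomeTable,
    rna: DifferentialTable,
    prot_lfc_thr: float = 0.5,
    rna_lfc_cap: float = 0.25,
    rna_fdr_floor: float = 0.05,
    min_conditions: int | None = None,
) -> list[SubstrateCall]:
    """Nominate stabilized-substrate candidates from paired tables.

    A gene is a candidate iff its mean protein log2FC across mutant
    conditions exceeds ``prot_lfc_thr`` AND its mRNA shows no concomitant
    increase (``rna_fdr >= rna_fdr_floor`` OR ``|rna_log2fc| <
    rna_lfc_cap``). With ``min_conditions=k`` the protein criterion must
    additionally hold in at least k individual mutant conditions
    (per-condition consistency mode). Genes missing from the RNA table are
    kept, decided on the protein criterion alone, and flagged ``no-rna``.

    Output is sorted by mean protein log2FC, descending; ties broken by
    gene_id so the order is independent of input row order.
    """
    means = prot.frame[prot.conditions].mean(axis=1)
    calls: list[SubstrateCall] = []
    for gene_id in prot.frame.index:
        mean_lfc = float(means.loc[gene_id])
        prot_ok = mean_lfc > prot_lfc_thr
        rule_bits = [f"mean_prot_lfc={mean_lfc:.3f}>{prot_lfc_thr}={prot_ok}"]
        if min_conditions is not None:
            n_hit = int(
                (prot.frame.loc[gene_id, prot.conditions] > prot_lfc_thr).sum()
            )
            prot_ok = prot_ok and n_hit >= min_conditions
            rule_bits.append(f"conditions_above={n_hit}>={min_conditions}")
        if gene_id in rna.frame.index:
            rna_lfc = float(rna.frame.at[gene_id, "log2fc"])
            rna_fdr = float(rna.frame.at[gene_id, "fdr"])
            rna_flat = rna_fdr >= rna_fdr_floor or abs(rna_lfc) < rna_lfc_cap
            rule_bits.append(
                f"rna_flat(fdr={rna_fdr:.3g}>={rna_fdr_floor} or "
                f"|lfc|={abs(rna_lfc):.3f}<{rna_lfc_cap})={rna_flat}"
            )
        else:
            rna_lfc = rna_fdr = None
            rna_flat = True
            rule_bits.append("no-rna")
        calls.append(
            SubstrateCall(
                gene_id=gene_id,
                mean_protein_log2fc=mean_lfc,
                rna_log2fc=rna_lfc,
                rna_fdr=rna_fdr,
                candidate=bool(prot_ok and rna_flat),
                rule="; ".join(rule_bits),
            )
        )
    calls.sort(key=lambda c: (-c.mean_protein_log2fc, c.gene_id))
    return calls


def calls_to_frame(calls: list[SubstrateCall]) -> pd.DataFrame:
    """Tabulate substrate calls (one row per protein, candidates first by
    protein effect)."""
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "mean_protein_log2fc": [c.mean_protein_log2fc for c in calls],
            "rna_log2fc": [
                np.nan if c.rna_log2fc is None else c.rna_log2fc for c in calls
            ],
            "rna_fdr": [np.nan if c.rna_fdr is None else c.rna_fdr for c in calls],
            "candidate": [c.candidate for c in calls],
            "rule": [c.rule for c in calls],
        }
    ).set_index("gene_id")
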