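"""Repertoire partitioning, paralog collapsing and gene-usage matrices.

The expressed repertoire is split into an *unmutated* set (V and J both
match the assigned germline allele at 100% identity; naive-enriched) and
a *mutated* set (any mismatch; antigen-experienced-enriched).  Usage is
the frequency of each gene among all unique records of a sample within
one partition.  Proximal/distal gene duplicates whose alleles cannot be
separated in a given individual are collapsed to an ambiguous ("ambi")
label for that individual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import UsageMatrix
from .simulate import GermlineSets, ParalogPairSpec

logger = logging.getLogger(__name__)


def gene_of(call: str) -> str:
    """Strip the allele suffix from a segment call (``V01*02`` -> ``V01``).

    Multi-gene calls (comma-separated aligner ties) resolve to the first
    listed gene.
    """
    first = call.split(",")[0]
    return first.split("*")[0]


def genes_of(calls: pd.Series) -> pd.Series:
    """Vectorised :func:`gene_of` (factorised so each distinct call is
    parsed once)."""
    codes, uniques = pd.factorize(calls)
    mapped = np.array([gene_of(u) for u in uniques], dtype=object)
    return pd.Series(mapped[codes], index=calls.index)


def partition_by_mutation(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Split records into (unmutated, mutated) sets.

    A record is unmutated iff ``v_identity == 100 and j_identity == 100``,
    mutated otherwise.  Records with a missing identity are dropped; their
    count is returned and logged.
    """
    ok = records["v_identity"].notna() & records["j_identity"].notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("partition_by_mutation: dropped %d records with missing identity", n_dropped)
    kept = records.loc[ok]
    unmut_mask = (kept["v_identity"] == 100) & (kept["j_identity"] == 100)
    return kept.loc[unmut_mask].copy(), kept.loc[~unmut_mask].copy(), n_dropped


def is_disambiguable(germline: GermlineSets, sample: str, pair: ParalogPairSpec) -> bool:
    """An individual can separate a paralog pair iff its proximal and
    distal allele sets are disjoint (a deleted paralog is trivially
    disjoint)."""
    prox = set(germline.alleles_of(sample, pair.proximal))
    dist = set(germline.alleles_of(sample, pair.distal))
    return len(prox & dist) == 0


def collapse_call(gene: str, ambi_map: dict[str, str], disambiguable: bool = False) -> str:
    """Rewrite a gene label to its ambi group label unless the individual
    is disambiguable for that group; unmapped labels pass through."""
    if gene in ambi_map and not disambiguable:
        return ambi_map[gene]
    return gene


def collapse_paralogs(
    records: pd.DataFrame,
    pairs: list[ParalogPairSpec],
    germline: GermlineSets | None = None,
) -> pd.DataFrame:
    """Add collapsed ``v_gene``/``j_gene`` columns to a record table.

    For each paralog pair, records from individuals that cannot separate
    the pair are relabelled to the pair's ambi label; disambiguable
    individuals keep the specific gene labels.  Idempotent.
    """
    out = records.copy()
    for axis in ("v", "j"):
        out[f"{axis}_gene"] = genes_of(out[f"{axis}_call"])
    if not pairs:
        return out
    ambi_map = {}
    for p in pairs:
        ambi_map[p.proximal] = p.label
        ambi_map[p.distal] = p.label
    if germline is None:
        disamb_samples: dict[str, set[str]] = {}
    else:
        disamb_samples = {
            s: {p.label for p in pairs if is_disambiguable(germline, s, p)}
            for s in {str(x) for x in out["sample_id"].unique()}
        }
    all_samples = {str(x) for x in out["sample_id"].unique()}
    decision = {
        (s, g): (g if label in disamb_samples.get(s, ()) else label)
        for s in all_samples
        for g, label in ambi_map.items()
    }
    for axis in ("v", "j"):
        col = out[f"{axis}_gene"]
        needs = col.isin(ambi_map).to_numpy()
        if needs.any():
            idx = out.index[needs]
            out.loc[idx, f"{axis}_gene"] = [
                decision[(s, g)]
                for s, g in zip(out.loc[idx, "sample_id"], col.loc[idx])
            ]
    return out


def compute_usage(
    records: pd.DataFrame,
    axis: str = "v",
    min_gene_count: int = 10,
    min_sample_seqs: int = 100,
    partition: str = "unmutated",
) -> UsageMatrix:
    """Gene x sample usage matrix over unique records.

    Samples with fewer than ``min_sample_seqs`` unique records are
    excluded.  Frequencies are computed against the total unique records
    of each retained sample *before* the gene filter, so the denominator
    includes genes that are later dropped.  Genes are retained iff their
    count reaches ``min_gene_count`` in at least one retained sample.
    Duplicate counts never enter the computation: each row is one unique
    record.
    """
    if axis not in ("v", "j"):
        raise ValueError("axis must be 'v' or 'j'")
    gene_col = f"{axis}_gene"
    if records.empty:
        empty = pd.DataFrame(dtype=float)
        return UsageMatrix(empty, empty.copy(), partition, {"dropped_samples": [], "dropped_genes": []})
    work = records if gene_col in records.columns else records.assign(
        **{gene_col: genes_of(records[f"{axis}_call"])}
    )
    totals = work.groupby("sample_id", observed=True).size()
    keep_samples = totals.index[totals >= min_sample_seqs]
    dropped_samples = sorted(set(totals.index) - set(keep_samples))
    work = work[work["sample_id"].isin(keep_samples)]
    if work.empty:
        empty = pd.DataFrame(dtype=float)
        return UsageMatrix(empty, empty.copy(), partition,
                           {"dropped_samples": dropped_samples, "dropped_genes": []})
    counts = pd.crosstab(work[gene_col], work["sample_id"])
    counts = counts.reindex(columns=sorted(keep_samples), fill_value=0)
    counts.index.name = "gene"
    freq = counts / counts.sum(axis=0)
    keep_genes = counts.max(axis=1) >= min_gene_count
    dropped_genes = sorted(counts.index[~keep_genes])
    provenance = {
        "axis": axis,
        "min_gene_count": min_gene_count,
        "min_sample_seqs": min_sample_seqs,
        "dropped_samples": dropped_samples,
        "dropped_genes": dropped_genes,
    }
    return UsageMatrix(freq.loc[keep_genes].copy(), counts.loc[keep_genes].copy(),
                       partition, provenance)


def mask_paralog_usage(
    usage: UsageMatrix,
    pairs: list[ParalogPairSpec],
    germline: GermlineSets,
) -> UsageMatrix:
    """Mark non-evaluable paralog cells as missing.

    For each pair: the specific proximal/distal gene rows are NaN for
    individuals that cannot disambiguate the pair (their records went to
    the ambi label), and the ambi row is NaN for individuals that can
    (their records kept specific labels).  Association tests then drop
    those individuals pairwise instead of treating structural zeros as
    biological absence.
    """
    freq = usage.frequency.copy()
    for p in pairs:
        disamb = np.array([
            s in germline.assignments and is_disambiguable(germline, s, p)
            for s in freq.columns
        ])
        for gene in (p.proximal, p.distal):
            if gene in freq.index:
                freq.loc[gene, freq.columns[~disamb]] = np.nan
        if p.label in freq.index:
            freq.loc[p.label, freq.columns[disamb]] = np.nan
    return UsageMatrix(freq, usage.count, usage.partition, dict(usage.provenance))
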