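"""Planted-truth recovery harness.

Utilities that run the analysis stack on simulated cohorts and score it
against the generator's truth table: lead-class recovery of causal
variants, fold-change accuracy, family-wise false-positive rates under a
null cohort, exact recovery of planted LD blocks, property-QTL
co-identification, and planted-clique recovery.  These are the package's
own validation instruments; the test suite and the reproduction script
are thin wrappers around them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ld, networks, properties, qtl, usage
from .simulate import (
    AlleleSpec,
    BlockSpec,
    GeneSpec,
    SimConfig,
    SimResult,
    emit_genotypes,
    simulate_haplotypes,
)


@dataclass
class CohortAnalysis:
    usage_v: "pd.DataFrame"
    common: object
    classes: list
    guqtl: pd.DataFrame
    property_means: pd.DataFrame | None = None
    property_qtls: pd.DataFrame | None = None


def analyse(sim: SimResult, alpha: float = 0.05, with_properties: bool = False) -> CohortAnalysis:
    """Usage -> (properties) -> MAF filter -> LD collapse -> QTL scan."""
    unmut, _, _ = usage.partition_by_mutation(sim.records)
    collapsed = usage.collapse_paralogs(unmut, sim.config.paralog_pairs, sim.germline)
    um = usage.compute_usage(collapsed, axis="v")
    um = usage.mask_paralog_usage(um, sim.config.paralog_pairs, sim.germline)
    common = qtl.filter_common(sim.genotypes)
    classes = qtl.collapse_perfect_ld(common)
    table = qtl.map_guqtls(um, common, classes, alpha=alpha)
    means = pq = None
    if with_properties:
        means = properties.sample_mean_properties(unmut)
        pq = qtl.map_property_qtls(means, common, classes, alpha=alpha)
    return CohortAnalysis(um, common, classes, table, means, pq)


def causal_lead_recovery(analysis: CohortAnalysis, sim: SimResult) -> pd.DataFrame:
    """Per causal variant: is its LD class the lead for the target gene,
    and how close is the measured fold change to the planted one
    (``exp(2 * beta)``)?"""
    leads = analysis.guqtl[analysis.guqtl["lead"]]
    rows = []
    for vid, gene, beta in sim.truth.effects():
        planted_fold = float(np.exp(2.0 * abs(beta)))
        row = leads[leads["gene"] == gene]
        lead_ok = False
        fold = np.nan
        rel_err = np.nan
        if len(row) == 1:
            members = row.iloc[0]["member_ids"].split(",")
            lead_ok = vid in members
            fold = row.iloc[0]["fold_change"]
            if np.isfinite(fold):
                rel_err = abs(fold - planted_fold) / planted_fold
        rows.append(
            {"variant": vid, "gene": gene, "lead_recovered": lead_ok,
             "fold_change": fold, "planted_fold": planted_fold,
             "fold_rel_err": rel_err}
        )
    return pd.DataFrame(rows)


def gene_false_positive_fraction(analysis: CohortAnalysis, sim: SimResult) -> tuple[int, int]:
    """(genes with >= 1 significant guQTL that are NOT targets of any
    planted effect or SV, total non-target genes tested)."""
    planted = {g for _, g, _ in sim.truth.effects()}
    for sv in sim.config.svs:
        planted.update(sv.genes)
    tested = [g for g in analysis.guqtl["gene"].unique() if g not in planted]
    sig = set(analysis.guqtl[analysis.guqtl["significant"]]["gene"].unique())
    return sum(g in sig for g in tested), len(tested)


def property_lead_recovery(analysis: CohortAnalysis, sim: SimResult) -> dict:
    """For each planted property effect: is the causal variant inside the
    lead property-QTL class, and is it also a significant guQTL variant
    for the driver gene?"""
    assert analysis.property_qtls is not None
    out = {}
    for prop, vid in sim.truth.planted_property_effects.items():
        gene = sim.truth.causal_variants[vid][0][0]
        lead = analysis.property_qtls[
            (analysis.property_qtls["property"] == prop) & analysis.property_qtls["lead"]
        ]
        lead_ok = (
            len(lead) == 1 and vid in lead.iloc[0]["member_ids"].split(",")
        )
        gene_sets = networks.guqtl_sets(analysis.guqtl)
        co_guqtl = vid in gene_sets.get(gene, set())
        out[prop] = {"lead_recovered": lead_ok, "co_guqtl": co_guqtl}
    return out


def planted_clique_recovery(analysis: CohortAnalysis, sim: SimResult, k: int) -> dict:
    """Does the shared-guQTL network contain the planted k-gene set as a
    maximal clique?"""
    # the planted clique is the set of genes driven by the shared variant
    by_variant = {vid: [g for g, _ in pairs]
                  for vid, pairs in sim.truth.causal_variants.items()}
    shared_vid = max(by_variant, key=lambda v: len(by_variant[v]))
    driven = sorted(set(by_variant[shared_vid]))
    sets = networks.guqtl_sets(analysis.guqtl)
    graph = networks.build_graph(sets)
    structure = networks.find_structure(graph)
    return {
        "planted_genes": driven,
        "is_maximal_clique": driven in structure.cliques,
        "largest_clique_size": max((len(c) for c in structure.cliques), default=0),
        "n_driven": len(driven),
        "k": k,
    }


# ---------------------------------------------------------------------------
# LD-block recovery loci
# ---------------------------------------------------------------------------

def block_locus_config(seed: int, n_blocks: int = 5, variants_per_block: int = 10,
                       n_individuals: int = 120) -> SimConfig:
    """A small locus of two-founder planted blocks separated by free
    recombination, for exact boundary-recovery checks."""
    genes = [
        GeneSpec(f"V{i}", 1000 + i, "V", [AlleleSpec("01", "ATGGCT", "CAAA")], [1.0])
        for i in range(2)
    ] + [
        GeneSpec(f"J{i}", 9000 + i, "J", [AlleleSpec("01", "ATGGCT", "TF")], [1.0])
        for i in range(2)
    ]
    blocks = [
        BlockSpec(5_000 + 15_000 * b, 5_000 + 15_000 * b + 10_000, variants_per_block, 2)
        for b in range(n_blocks)
    ]
    return SimConfig(
        n_individuals=n_individuals,
        locus_span=5_000 + 15_000 * n_blocks + 10_000,
        blocks=blocks,
        genes=genes,
        seed=seed,
    )


def block_recovery(seed: int, **kwargs) -> bool:
    """True iff Gabriel blocks on one simulated locus equal the planted
    blocks exactly at the variant-index level."""
    cfg = block_locus_config(seed, **kwargs)
    panel = simulate_haplotypes(cfg)
    gm, _ = emit_genotypes(panel, cfg)
    pairs = ld.pairwise_ld(gm)
    cls = ld.classification_matrix(pairs, gm.n_variants)
    blocks = ld.gabriel_blocks(gm.variants["pos"].to_numpy(), cls, ids=gm.ids)
    expected = []
    offset = 0
    for spec in cfg.blocks:
        expected.append((offset, offset + spec.n_variants - 1))
        offset += spec.n_variants
    found = [(b.member_indices[0], b.member_indices[-1]) for b in blocks]
    return sorted(found) == sorted(expected)


# ---------------------------------------------------------------------------
# regression calibration
# ---------------------------------------------------------------------------

def null_regression_pvalues(seed: int, n: int = 170, n_tests: int = 10_000,
                            maf: float = 0.3, chunk: int = 500) -> np.ndarray:
    """P-values from the package's OLS for traits independent of dosage
    (a fresh trait and dosage draw per test)."""
    rng = np.random.default_rng(seed)
    out = []
    for start in range(0, n_tests, chunk):
        m = min(chunk, n_tests - start)
        X = rng.binomial(2, maf, size=(m, n)).astype(float)
        Y = rng.normal(size=(m, n))
        res = qtl._regress_many(Y, X)
        out.append(np.diagonal(res["p"]))
    p = np.concatenate(out)
    return p[np.isfinite(p)]
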