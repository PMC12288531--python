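"""Coding-allele / guQTL-genotype linkage.

For each gene with a lead guQTL, counts coding-allele copies across the
three lead-variant genotype groups and asks (Fisher's exact test)
whether allele composition differs between groups.  Counts are allele
*copies* — two per diploid individual, fewer under copy-number deletion
— which keeps table margins stable; carriage percentages are a display
concern.  Genes whose major allele exceeds 95% cohort frequency lack
appreciable allelic variation and are flagged instead of tested.

The 2x2 test is the exact two-sided hypergeometric (point-probability
method).  r x c tables use the exact Freeman-Halton sum when full
enumeration fits a node budget, otherwise seeded Monte Carlo over
margin-preserving tables (Patefield sampling) with the MC standard
error reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .containers import GenotypeMatrix
from .simulate import GermlineSets

logger = logging.getLogger(__name__)

_REL_TOL = 1e-7


@dataclass
class FisherResult:
    p_value: float
    method: str  # "exact-2x2" | "exact-rxc" | "monte-carlo"
    mc_se: float = 0.0
    n_mc: int = 0


def _fisher_2x2(table: np.ndarray) -> float:
    """Two-sided 2x2 Fisher probability by the point-probability method:
    sum of all hypergeometric outcomes no more likely than the observed."""
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + _REL_TOL)].sum())


class _BudgetExceeded(Exception):
    pass


def _fisher_rxc_exact(table: np.ndarray, node_budget: int) -> float:
    """Freeman-Halton exact probability by enumeration of all tables with
    the observed margins; raises _BudgetExceeded beyond the budget."""
    table = np.asarray(table, dtype=np.int64)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())
    const = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1)
    logp_obs = const - gammaln(table + 1).sum()

    total = 0.0
    count = 0

    def rec(r: int, remaining_cols: np.ndarray, acc: float) -> None:
        nonlocal total, count
        if r == len(rows) - 1:
            count += 1
            if count > node_budget:
                raise _BudgetExceeded
            logp = const - acc - gammaln(remaining_cols + 1).sum()
            if logp <= logp_obs + _REL_TOL:
                total += np.exp(logp)
            return
        target = int(rows[r])

        def comp(c: int, left: int, rem: np.ndarray, acc2: float) -> None:
            nonlocal count
            if c == len(cols) - 1:
                if left <= rem[c]:
                    count += 1
                    if count > node_budget:
                        raise _BudgetExceeded
                    new_rem = rem.copy()
                    new_rem[c] -= left
                    rec(r + 1, new_rem, acc2 + gammaln(left + 1))
                return
            for x in range(min(left, int(rem[c])) + 1):
                new_rem = rem.copy()
                new_rem[c] -= x
                comp(c + 1, left - x, new_rem, acc2 + gammaln(x + 1))

        comp(0, target, remaining_cols, acc)

    rec(0, cols.astype(np.int64), 0.0)
    return float(min(total, 1.0))


def _fisher_rxc_mc(table: np.ndarray, rng: np.random.Generator, n_mc: int) -> tuple[float, float]:
    """Monte-Carlo Freeman-Halton p-value over Patefield-sampled tables."""
    table = np.asarray(table, dtype=np.int64)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())
    const = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1)
    logp_obs = const - gammaln(table + 1).sum()
    sampler = stats.random_table(rows, cols)
    draws = sampler.rvs(n_mc, random_state=rng)
    logp = const - gammaln(draws + 1).sum(axis=(1, 2))
    hits = int((logp <= logp_obs + _REL_TOL).sum())
    p = (hits + 1) / (n_mc + 1)
    se = float(np.sqrt(p * (1 - p) / n_mc))
    return float(p), se


def fisher_exact(
    table,
    seed: int = 0,
    n_mc: int = 100_000,
    node_budget: int = 2_000_000,
) -> FisherResult:
    """Two-sided Fisher exact test for an r x c contingency table.

    2x2 tables use the exact hypergeometric point-probability method.
    Larger tables are enumerated exactly while the enumeration fits
    ``node_budget`` nodes, otherwise a seeded Monte Carlo over
    margin-preserving tables is used (``n_mc`` draws), with the
    estimator's standard error reported.
    Degenerate margins (an all-zero row/column or a single
    row/column) are not testable and raise ValueError.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (table < 0).any():
        raise ValueError("negative counts")
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate margins: fewer than 2 informative rows/columns")
    if table.shape == (2, 2):
        return FisherResult(p_value=_fisher_2x2(table), method="exact-2x2")
    try:
        p = _fisher_rxc_exact(table, node_budget)
        return FisherResult(p_value=p, method="exact-rxc")
    except _BudgetExceeded:
        rng = np.random.default_rng(seed)
        p, se = _fisher_rxc_mc(table, rng, n_mc)
        logger.info("fisher_exact: enumeration over budget, Monte Carlo with "
                    "%d tables (se %.2g)", n_mc, se)
        return FisherResult(p_value=p, method="monte-carlo", mc_se=se, n_mc=n_mc)


# ---------------------------------------------------------------------------
# allele x genotype tables
# ---------------------------------------------------------------------------

def allele_genotype_table(
    germline: GermlineSets,
    gene: str,
    lead_dosage: pd.Series,
) -> pd.DataFrame:
    """Allele-copy counts (rows: cohort alleles of ``gene``) by lead-guQTL
    genotype group (columns: dosage 0/1/2).

    Each individual contributes one count per retained gene copy, so a
    copy-number-1 individual contributes a single allele copy.
    """
    if not any(gene in per_gene for per_gene in germline.assignments.values()):
        raise KeyError(f"gene {gene!r} absent from germline allele sets")
    alleles = sorted(germline.cohort_allele_counts(gene))
    table = pd.DataFrame(0, index=alleles, columns=[0, 1, 2])
    for sample, dosage in lead_dosage.items():
        if sample not in germline.assignments or np.isnan(dosage):
            continue
        group = int(dosage)
        for a in germline.alleles_of(sample, gene):
            table.loc[a, group] += 1
    return table


def low_variation_filter(germline: GermlineSets, gene: str, threshold: float = 0.95) -> bool:
    """True iff the gene's most frequent coding allele exceeds
    ``threshold`` cohort frequency (strict), including the single-allele
    case — such genes lack appreciable allelic variation."""
    counts = germline.cohort_allele_counts(gene)
    total = sum(counts.values())
    if total == 0:
        return True
    if len(counts) == 1:
        return True
    return max(counts.values()) / total > threshold


def missense_or_nonsense(germline: GermlineSets, gene: str) -> bool:
    """True iff any two cohort alleles of the gene translate to different
    protein sequences (the allele difference is missense or nonsense)."""
    from Bio.Seq import Seq

    seqs = germline.sequences.get(gene, {})
    present = sorted(germline.cohort_allele_counts(gene))
    prots = {str(Seq(seqs[a]).translate()) for a in present if a in seqs}
    return len(prots) > 1


def test_allele_linkage(
    germline: GermlineSets,
    guqtl_results: pd.DataFrame,
    genotypes: GenotypeMatrix,
    alpha: float = 0.05,
    low_variation_threshold: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Fisher linkage test for every gene with a lead guQTL present in the
    germline sets.  Bonferroni threshold = alpha / number of genes
    actually tested (low-variation and degenerate-table genes are
    reported but excluded from the denominator)."""
    leads = guqtl_results[guqtl_results["lead"]]
    rows = []
    for _, lead in leads.iterrows():
        gene = lead["gene"]
        if not any(gene in per_gene for per_gene in germline.assignments.values()):
            continue
        low_var = low_variation_filter(germline, gene, low_variation_threshold)
        dosage = pd.Series(genotypes.row(lead["class_rep"]), index=genotypes.samples)
        table = allele_genotype_table(germline, gene, dosage)
        informative = table.loc[table.sum(axis=1) > 0, table.columns[table.sum(axis=0) > 0]]
        testable = (not low_var) and informative.shape[0] >= 2 and informative.shape[1] >= 2
        if testable:
            res = fisher_exact(informative.to_numpy(), seed=seed)
            p, method = res.p_value, res.method
        else:
            p, method = np.nan, "not-tested"
        rows.append(
            {
                "gene": gene,
                "lead_variant": lead["class_rep"],
                "p_value": p,
                "method": method,
                "tested": testable,
                "low_variation": low_var,
                "missense_or_nonsense": missense_or_nonsense(germline, gene),
                "table_json": table.to_json(),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    n_tested = int(out["tested"].sum())
    threshold = alpha / max(n_tested, 1)
    out["threshold"] = threshold
    out["significant"] = out["tested"] & (out["p_value"] < threshold)
    return out
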