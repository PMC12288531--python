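"""Gene-usage QTL mapping.

Associations between additive variant dosages (0/1/2 alternate-allele
copies for SNVs; diploid gene copy number for SVs) and per-sample traits
(gene-usage frequencies or CDR3-property means) by ordinary least
squares with an intercept.  Multiple testing is Bonferroni-corrected per
gene using the number of *effective* tests: variants in complete LD
(genotype r-squared = 1) collapse to a single variant class, and all
genes of a locus/partition share the resulting threshold.

Workflow: :func:`filter_common` -> :func:`collapse_perfect_ld` ->
:func:`map_guqtls` / :func:`map_property_qtls`, plus region annotation
and one-sided Fisher interval enrichment for the significant sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, UsageMatrix

logger = logging.getLogger(__name__)

REGION_PRIORITY = [
    "RSS-heptamer", "RSS-spacer", "RSS-nonamer", "V-exon", "L-Part1", "intron",
]


# ---------------------------------------------------------------------------
# variant filtering and perfect-LD collapsing
# ---------------------------------------------------------------------------

def filter_common(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.10,
) -> GenotypeMatrix:
    """Retain variants with cohort MAF >= ``maf_min`` (inclusive) and
    missingness <= ``max_missing``.  MAF is ``min(p, 1 - p)`` with
    ``p`` = mean dosage / 2 over non-missing individuals."""
    keep = (genotypes.maf() >= maf_min) & (genotypes.missing_rate() <= max_missing)
    return genotypes.subset(keep)


@dataclass
class LDClass:
    """A set of variants in complete pairwise LD, represented by the
    member at the lowest genomic position."""

    rep_id: str
    rep_index: int
    position: int
    member_ids: list[str]


def collapse_perfect_ld(genotypes: GenotypeMatrix, tol: float = 1e-12) -> list[LDClass]:
    """Partition variants into complete-LD classes (pairwise r^2 = 1
    within ``tol``); returns classes sorted by representative position.

    Perfect correlation is transitive, so classes are the connected
    components of the r^2 = 1 graph.  A zero-variance variant (impossible
    after the MAF filter) raises.
    """
    D = genotypes.dosage
    if np.isnan(D).any():
        # pairwise-complete correlation
        corr = pd.DataFrame(D.T).corr().to_numpy()
    else:
        sd = D.std(axis=1)
        if np.any(sd == 0):
            bad = genotypes.variants["id"][sd == 0].tolist()
            raise ValueError(f"zero-variance variants: {bad}")
        corr = np.corrcoef(D)
    corr = np.atleast_2d(corr)  # single-variant input collapses to 0-d
    r2 = corr**2
    adj = r2 >= 1.0 - tol
    from scipy.sparse.csgraph import connected_components

    n_comp, labels = connected_components(adj, directed=False)
    classes = []
    pos = genotypes.variants["pos"].to_numpy()
    ids = genotypes.variants["id"].to_numpy()
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        rep = members[np.argmin(pos[members])]
        classes.append(
            LDClass(
                rep_id=str(ids[rep]),
                rep_index=int(rep),
                position=int(pos[rep]),
                member_ids=[str(ids[m]) for m in members],
            )
        )
    classes.sort(key=lambda cl: (cl.position, cl.rep_id))
    return classes


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    beta: float
    se: float
    p_value: float
    adjusted_r2: float
    n: int
    testable: bool = True


def regress(trait: np.ndarray, dosage: np.ndarray) -> RegressionResult:
    """OLS of trait on dosage with intercept.

    Two-sided t-test on the slope; adjusted R-squared with the standard
    small-sample correction.  Constant dosage or trait (or n < 3) yields
    a non-testable result rather than an exception.  Missing values are
    dropped pairwise.
    """
    y = np.asarray(trait, dtype=float)
    x = np.asarray(dosage, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(x))
    y, x = y[ok], x[ok]
    n = len(y)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return RegressionResult(np.nan, np.nan, np.nan, np.nan, n, testable=False)
    res = _regress_many(y[None, :], x[None, :])
    return RegressionResult(
        beta=float(res["beta"][0, 0]),
        se=float(res["se"][0, 0]),
        p_value=float(res["p"][0, 0]),
        adjusted_r2=float(res["adj_r2"][0, 0]),
        n=n,
    )


def _regress_many(Y: np.ndarray, X: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised simple OLS of every row of Y on every row of X.

    Y: (G, n) traits, X: (M, n) dosages, NaN = missing (dropped
    pairwise).  Returns (G, M) arrays beta, se, p, adj_r2, n, plus
    genotype-group means/counts for dosage groups 0/1/2.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    Vy = ~np.isnan(Y)
    Vx = ~np.isnan(X)
    Y0 = np.where(Vy, Y, 0.0)
    X0 = np.where(Vx, X, 0.0)

    V = Vy[:, None, :] & Vx[None, :, :]  # (G, M, n)
    n = V.sum(axis=2).astype(float)
    Sx = np.einsum("gmn,mn->gm", V, X0)
    Sxx = np.einsum("gmn,mn->gm", V, X0 * X0)
    Sy = np.einsum("gmn,gn->gm", V, Y0)
    Syy = np.einsum("gmn,gn->gm", V, Y0 * Y0)
    Sxy = np.einsum("gmn,gn,mn->gm", V, Y0, X0)

    with np.errstate(invalid="ignore", divide="ignore"):
        Sxx_c = Sxx - Sx * Sx / n
        Syy_c = Syy - Sy * Sy / n
        Sxy_c = Sxy - Sx * Sy / n
        beta = Sxy_c / Sxx_c
        sse = np.clip(Syy_c - beta * Sxy_c, 0.0, None)
        df = n - 2
        se = np.sqrt(sse / df / Sxx_c)
        t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        r2 = 1.0 - sse / Syy_c
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df

    scale = max(np.nanmax(np.abs(X0)), 1.0)
    testable = (n >= 3) & (Sxx_c > 1e-12 * scale * n) & (Syy_c > 0)
    for arr in (beta, se, p, adj_r2):
        arr[~testable] = np.nan

    groups = {}
    for g in (0, 1, 2):
        W = Vx & (X0 == g)  # (M, n); X0==g is only meaningful where Vx
        cnt = np.einsum("gmn,mn->gm", V, W.astype(float))
        tot = np.einsum("gmn,gn,mn->gm", V, Y0, W.astype(float))
        with np.errstate(invalid="ignore"):
            groups[g] = {"mean": np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan),
                         "count": cnt}
    return {
        "beta": beta, "se": se, "p": p, "adj_r2": adj_r2, "n": n,
        "testable": testable, "groups": groups,
    }


def fold_change(trait: np.ndarray, dosage: np.ndarray) -> tuple[float, str]:
    """Ratio (>= 1) of the larger homozygote-group mean trait to the
    smaller, between dosage groups 0 and 2.

    Returns ``(value, flag)``: flag ``"ok"``, ``"max"`` (smaller mean is
    zero; value is +inf), or ``"undefined"`` (an empty homozygote group;
    value NaN — no heterozygote fallback)."""
    y = np.asarray(trait, dtype=float)
    x = np.asarray(dosage, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(x))
    m0 = y[ok & (x == 0)]
    m2 = y[ok & (x == 2)]
    if len(m0) == 0 or len(m2) == 0:
        return np.nan, "undefined"
    lo, hi = sorted([m0.mean(), m2.mean()])
    if hi == lo:
        return 1.0, "ok"
    if lo == 0:
        return np.inf, "max"
    return hi / lo, "ok"


# ---------------------------------------------------------------------------
# QTL mapping
# ---------------------------------------------------------------------------

def _map_traits(
    traits: pd.DataFrame,
    genotypes: GenotypeMatrix,
    classes: list["LDClass"],
    alpha: float,
    trait_kind: str,
) -> pd.DataFrame:
    """Shared mapper: one OLS per trait x LD-class representative."""
    common = [s for s in traits.columns if s in genotypes.samples]
    if len(common) < 3:
        raise ValueError("fewer than 3 samples shared between traits and genotypes")
    col_idx = [genotypes.samples.index(s) for s in common]
    X = genotypes.dosage[np.ix_([c.rep_index for c in classes], col_idx)]
    Y = traits[common].to_numpy(dtype=float)

    res = _regress_many(Y, X)
    k = len(classes)
    threshold = alpha / k
    rows = []
    for gi, trait_name in enumerate(traits.index):
        skipped = res["testable"][gi]
        if not skipped.any():
            logger.info("%s %r: no testable variant class (constant trait?)",
                        trait_kind, trait_name)
        for ci, cl in enumerate(classes):
            p = res["p"][gi, ci]
            sig = bool(np.isfinite(p) and p < threshold)
            m0 = res["groups"][0]["mean"][gi, ci]
            m2 = res["groups"][2]["mean"][gi, ci]
            c0 = res["groups"][0]["count"][gi, ci]
            c2 = res["groups"][2]["count"][gi, ci]
            if c0 == 0 or c2 == 0:
                fc, fc_flag = np.nan, "undefined"
            else:
                lo, hi = sorted([m0, m2])
                if hi == lo:
                    fc, fc_flag = 1.0, "ok"
                elif lo == 0:
                    fc, fc_flag = np.inf, "max"
                else:
                    fc, fc_flag = hi / lo, "ok"
            rows.append(
                {
                    trait_kind: trait_name,
                    "class_rep": cl.rep_id,
                    "position": cl.position,
                    "member_ids": ",".join(cl.member_ids),
                    "n_members": len(cl.member_ids),
                    "beta": res["beta"][gi, ci],
                    "se": res["se"][gi, ci],
                    "p_value": p,
                    "adjusted_r2": res["adj_r2"][gi, ci],
                    "n": int(res["n"][gi, ci]),
                    "testable": bool(res["testable"][gi, ci]),
                    "significant": sig,
                    "fold_change": fc,
                    "fold_change_flag": fc_flag,
                    "mean_dosage0": m0,
                    "mean_dosage1": res["groups"][1]["mean"][gi, ci],
                    "mean_dosage2": m2,
                }
            )
    out = pd.DataFrame(rows)
    out["n_effective_tests"] = k
    out["threshold"] = threshold

    # lead: minimum p among significant classes; ties by position then id
    out["lead"] = False
    for trait_name, sub in out[out["significant"]].groupby(trait_kind):
        ordered = sub.sort_values(["p_value", "position", "class_rep"])
        out.loc[ordered.index[0], "lead"] = True
    return out


def map_guqtls(
    usage: UsageMatrix,
    genotypes: GenotypeMatrix,
    classes: list[LDClass],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Gene-usage QTL scan: one test per gene x LD-class representative.

    The per-gene Bonferroni threshold is ``alpha / n_effective_tests``
    with the effective count shared locus-wide.  Member variants inherit
    their class result.  Exactly one lead class (lowest p, ties by
    genomic position then id) is flagged per gene with at least one
    significant class.
    """
    return _map_traits(usage.frequency, genotypes, classes, alpha, "gene")


def map_property_qtls(
    properties: pd.DataFrame,
    genotypes: GenotypeMatrix,
    classes: list[LDClass],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """CDR3-property QTL scan; identical contract to :func:`map_guqtls`
    with per-sample property means as traits (samples x properties)."""
    return _map_traits(properties.T, genotypes, classes, alpha, "property")


# ---------------------------------------------------------------------------
# region annotation and interval enrichment
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) with a name column."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: BED end must exceed start")
            name = fields[3] if len(fields) > 3 else "."
            rows.append({"contig": fields[0], "start": start, "end": end, "name": name})
    return pd.DataFrame(rows, columns=["contig", "start", "end", "name"])


def annotate_variants(variants: pd.DataFrame, features: pd.DataFrame) -> pd.Series:
    """Assign a region label to each variant (1-based positions) from a
    0-based half-open feature table with labels in ``REGION_PRIORITY``.

    Overlapping features resolve by priority RSS > V-exon > L-Part1 >
    intron; positions outside every feature are ``intergenic``.
    """
    rank = {label: i for i, label in enumerate(REGION_PRIORITY)}
    labels = []
    for _, v in variants.iterrows():
        pos0 = int(v["pos"]) - 1
        hits = features[
            (features["contig"] == v["contig"])
            & (features["start"] <= pos0)
            & (pos0 < features["end"])
        ]
        if hits.empty:
            labels.append("intergenic")
        else:
            labels.append(min(hits["name"], key=lambda x: rank.get(x, len(rank))))
    return pd.Series(labels, index=variants.index, name="region_label")


@dataclass
class EnrichmentResult:
    odds_ratio: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]


def interval_enrichment(
    qtl_variants: set[str],
    background_variants: set[str],
    interval_members: set[str],
) -> EnrichmentResult:
    """One-sided Fisher exact test for QTL enrichment in an interval set.

    2x2 table of (QTL vs non-QTL background) x (in-interval vs not); the
    odds ratio uses a 0.5 continuity correction when any cell is zero.
    """
    if not background_variants:
        raise ValueError("empty background set")
    if not qtl_variants <= background_variants:
        raise ValueError("QTL variants must be a subset of the background")
    non_qtl = background_variants - qtl_variants
    a = len(qtl_variants & interval_members)
    b = len(qtl_variants) - a
    c = len(non_qtl & interval_members)
    d = len(non_qtl) - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        orat = 1.0  # a degenerate margin carries no enrichment information
    elif min(a, b, c, d) == 0:
        orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orat = (a * d) / (b * c)
    return EnrichmentResult(odds_ratio=float(orat), p_value=float(p),
                            table=((a, b), (c, d)))
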