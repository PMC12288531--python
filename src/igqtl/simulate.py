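"""Synthetic cohort generator with planted, recoverable ground truth.

The generator emulates a population cohort genotyped across an
immunoglobulin light-chain locus together with matched expressed
repertoires:

* **Haplotypes** follow a founder-block model: the locus is tiled by
  non-overlapping blocks, each block carries a small panel of founder
  haplotypes, and every individual haplotype is a copy of one founder per
  block (no intra-block recombination).  Founder choices are independent
  across blocks, giving free inter-block recombination.  This is the
  simplest generator that produces block-structured linkage
  disequilibrium with D' = 1 inside blocks and ~0 between them.
* **Gene usage** responds multiplicatively to planted causal variants:
  the sampling weight of gene *g* in individual *i* is
  ``baseline_g * exp(sum_e beta_e * dosage_i(e)) * cn_g(i) / 2``,
  so each additional alternate-allele copy multiplies usage by
  ``exp(beta)`` and usage scales additively with diploid gene copy
  number.  Records are drawn multinomially.
* **Junctions** are germline 3' V contribution + random insert +
  germline 5' J contribution, so the germline-encoded residues of a
  junction are constant for a fixed V/J allele pair.
* **Coding alleles** can be tagged to a variant so that the haplotype
  carrying the alternate allele also carries a specific coding allele,
  planting the allele/genotype linkage the analysis is meant to recover.

Everything is deterministic under ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_MAX_MAF_ROUNDS = 200


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class BlockSpec:
    """One LD block: bp interval, variant count and founder-panel size."""

    start: int
    end: int
    n_variants: int
    n_founders: int


@dataclass
class AlleleSpec:
    """A coding allele: name, coding nucleotide sequence, and the
    germline amino acids this allele contributes to the junction
    (3' end for V alleles, 5' end for J alleles)."""

    name: str
    coding_seq: str
    junction_aa: str


@dataclass
class GeneSpec:
    name: str
    position: int
    segment: str  # "V" or "J"
    alleles: list[AlleleSpec]
    allele_freqs: list[float]
    baseline_weight: float = 1.0


@dataclass
class ParalogPairSpec:
    """Proximal/distal gene duplicates sharing an allele pool, collapsed
    to ``label`` for individuals whose allele sets cannot separate them."""

    proximal: str
    distal: str
    label: str


@dataclass
class EffectSpec:
    """Per-copy multiplicative effect of a causal variant on one gene's
    log sampling weight."""

    variant_id: str
    gene: str
    beta: float


@dataclass
class SVSpec:
    """Deletion structural variant removing ``genes`` from carrier
    haplotypes; emitted as a diploid copy-number genotype."""

    id: str
    position: int
    genes: list[str]
    deletion_freq: float


@dataclass
class LinkageSpec:
    """Plant perfect linkage: haplotypes with the alternate allele at
    ``variant_id`` carry coding allele ``allele`` of ``gene``."""

    gene: str
    allele: str
    variant_id: str


@dataclass
class SimConfig:
    n_individuals: int
    locus_span: int
    blocks: list[BlockSpec]
    genes: list[GeneSpec]
    paralog_pairs: list[ParalogPairSpec] = field(default_factory=list)
    effects: list[EffectSpec] = field(default_factory=list)
    svs: list[SVSpec] = field(default_factory=list)
    linked_alleles: list[LinkageSpec] = field(default_factory=list)
    property_effects: dict[str, str] = field(default_factory=dict)
    repertoire_size: int = 5000
    repertoire_size_sd: float = 0.0
    usage_noise_sd: float = 0.3
    mutated_fraction: float = 0.3
    maf_floor: float = 0.05
    insert_len_mean: float = 3.0
    contig: str = "chrS"
    seed: int = 0

    def gene(self, name: str) -> GeneSpec:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(f"gene {name!r} not in gene_spec")

    def variant_ids(self) -> list[str]:
        out = []
        for b, spec in enumerate(self.blocks):
            out.extend(f"b{b}v{j}" for j in range(spec.n_variants))
        return out


def validate_config(config: SimConfig) -> None:
    """Check SimConfig invariants; raise ValueError on violation."""
    prev_end = -1
    for spec in config.blocks:
        if spec.start <= prev_end:
            raise ValueError("block intervals must be sorted and non-overlapping")
        if spec.end <= spec.start:
            raise ValueError("block end must exceed start")
        if spec.end > config.locus_span:
            raise ValueError("block extends past locus span")
        if spec.n_founders < 2:
            raise ValueError("each block needs at least 2 founder haplotypes")
        if spec.n_variants < 1:
            raise ValueError("each block needs at least 1 variant")
        prev_end = spec.end
    gene_names = {g.name for g in config.genes}
    for eff in config.effects:
        if eff.gene not in gene_names:
            raise ValueError(f"effect targets unknown gene {eff.gene!r}")
    vids = set(config.variant_ids())
    for eff in config.effects:
        if eff.variant_id not in vids:
            raise ValueError(f"effect references unknown variant {eff.variant_id!r}")
    for link in config.linked_alleles:
        if link.variant_id not in vids:
            raise ValueError(f"linkage references unknown variant {link.variant_id!r}")
        if link.gene not in gene_names:
            raise ValueError(f"linkage references unknown gene {link.gene!r}")
    for g in config.genes:
        if len(g.alleles) != len(g.allele_freqs):
            raise ValueError(f"gene {g.name}: allele/frequency length mismatch")
        if abs(sum(g.allele_freqs) - 1.0) > 1e-9:
            raise ValueError(f"gene {g.name}: allele frequencies must sum to 1")
    for sv in config.svs:
        if not 0.0 <= sv.deletion_freq <= 1.0:
            raise ValueError("SV deletion frequency outside [0, 1]")
        for gname in sv.genes:
            if gname not in gene_names:
                raise ValueError(f"SV {sv.id} affects unknown gene {gname!r}")
    if not 0.0 <= config.mutated_fraction <= 1.0:
        raise ValueError("mutated_fraction outside [0, 1]")
    if not 0.0 <= config.maf_floor < 0.5:
        raise ValueError("maf_floor outside [0, 0.5)")


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Planted ground truth for recovery tests.

    ``causal_variants`` maps each causal variant id to the list of
    (target gene, per-copy effect) pairs it drives — one variant may
    drive several genes (a planted co-regulation clique).
    """

    causal_variants: dict[str, list[tuple[str, float]]]
    block_boundaries: list[tuple[int, int]]
    linked_coding_alleles: dict[str, tuple[str, str]]
    planted_property_effects: dict[str, str]

    def effects(self):
        """Flat iterator of (variant_id, gene, beta)."""
        for vid, pairs in self.causal_variants.items():
            for gene, beta in pairs:
                yield vid, gene, beta

    def to_dict(self) -> dict:
        return {
            "causal_variants": {
                k: [list(p) for p in v] for k, v in self.causal_variants.items()
            },
            "block_boundaries": [list(b) for b in self.block_boundaries],
            "linked_coding_alleles": {k: list(v) for k, v in self.linked_coding_alleles.items()},
            "planted_property_effects": dict(self.planted_property_effects),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(
            causal_variants={
                k: [(p[0], float(p[1])) for p in v]
                for k, v in d["causal_variants"].items()
            },
            block_boundaries=[tuple(b) for b in d["block_boundaries"]],
            linked_coding_alleles={k: tuple(v) for k, v in d["linked_coding_alleles"].items()},
            planted_property_effects=dict(d["planted_property_effects"]),
        )


def build_truth(config: SimConfig) -> SimTruth:
    causal: dict[str, list[tuple[str, float]]] = {}
    for e in config.effects:
        causal.setdefault(e.variant_id, []).append((e.gene, e.beta))
    return SimTruth(
        causal_variants=causal,
        block_boundaries=[(b.start, b.end) for b in config.blocks],
        linked_coding_alleles={l.gene: (l.allele, l.variant_id) for l in config.linked_alleles},
        planted_property_effects=dict(config.property_effects),
    )


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePanel:
    """Phased haplotypes over all block variants.

    ``hap`` has shape (n_variants, 2 * n_individuals); haplotypes 2i and
    2i + 1 belong to individual i.  ``variants`` carries id, pos and the
    block index of each variant, sorted by position.
    """

    variants: pd.DataFrame
    hap: np.ndarray
    n_individuals: int


def _stage_rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), stage])


def simulate_haplotypes(config: SimConfig) -> HaplotypePanel:
    """Draw the phased founder-block haplotype panel.

    Within each block every individual haplotype copies one founder
    haplotype; founders are assigned independently across blocks.  Variants
    whose realised cohort MAF falls below ``config.maf_floor`` have their
    founder-allele column resampled (bounded rounds).  Variants referenced
    by effect or linkage specs get a balanced founder pattern (half of
    founders carry the alternate allele) so that planted signals sit at
    intermediate frequency.
    """
    validate_config(config)
    rng = _stage_rng(config, 0)
    n_hap = 2 * config.n_individuals
    balanced_ids = {e.variant_id for e in config.effects} | {
        l.variant_id for l in config.linked_alleles
    }

    rows = []
    hap_cols = []
    for b, spec in enumerate(config.blocks):
        positions = np.linspace(spec.start, spec.end, spec.n_variants).astype(int)
        # enforce unique integer positions inside the block
        positions = np.unique(positions)
        while len(positions) < spec.n_variants:
            extra = rng.integers(spec.start, spec.end + 1, spec.n_variants)
            positions = np.unique(np.concatenate([positions, extra]))[: spec.n_variants]
        positions = np.sort(positions[: spec.n_variants])

        founders = rng.integers(0, 2, size=(spec.n_founders, spec.n_variants)).astype(np.uint8)
        ids = [f"b{b}v{j}" for j in range(spec.n_variants)]
        for j, vid in enumerate(ids):
            if vid in balanced_ids:
                pattern = np.zeros(spec.n_founders, dtype=np.uint8)
                pattern[: spec.n_founders // 2 + spec.n_founders % 2] = 1
                rng.shuffle(pattern)
                founders[:, j] = pattern
        assignment = rng.integers(0, spec.n_founders, size=n_hap)
        block_hap = founders[assignment, :]  # (n_hap, n_variants)

        freqs = block_hap.mean(axis=0)
        rounds = 0
        bad = np.flatnonzero(np.minimum(freqs, 1 - freqs) < config.maf_floor)
        while len(bad) > 0:
            rounds += 1
            if rounds > _MAX_MAF_ROUNDS:
                raise RuntimeError(
                    f"block {b}: could not reach MAF floor {config.maf_floor} "
                    f"after {_MAX_MAF_ROUNDS} founder resampling rounds"
                )
            for j in bad:
                founders[:, j] = rng.integers(0, 2, size=spec.n_founders)
            block_hap = founders[assignment, :]
            freqs = block_hap.mean(axis=0)
            bad = np.flatnonzero(np.minimum(freqs, 1 - freqs) < config.maf_floor)

        rows.append(pd.DataFrame({"id": ids, "pos": positions, "block": b}))
        hap_cols.append(block_hap.T)  # (n_variants, n_hap)

    variants = pd.concat(rows, ignore_index=True)
    hap = np.vstack(hap_cols).astype(np.uint8)
    return HaplotypePanel(variants=variants, hap=hap, n_individuals=config.n_individuals)


# ---------------------------------------------------------------------------
# genotypes, SVs, germline allele sets
# ---------------------------------------------------------------------------

@dataclass
class GermlineSets:
    """Per-individual germline coding-allele sets.

    ``assignments[sample][gene]`` lists one allele name per retained gene
    copy (length equals diploid copy number, 0..2).  ``sequences`` and
    ``junction_contrib`` are gene -> allele -> string registries.
    """

    assignments: dict[str, dict[str, list[str]]]
    sequences: dict[str, dict[str, str]]
    junction_contrib: dict[str, dict[str, str]]

    def copy_number(self, sample: str, gene: str) -> int:
        return len(self.assignments[sample].get(gene, []))

    def alleles_of(self, sample: str, gene: str) -> list[str]:
        return self.assignments[sample].get(gene, [])

    def cohort_allele_counts(self, gene: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        for per_gene in self.assignments.values():
            for a in per_gene.get(gene, []):
                counts[a] = counts.get(a, 0) + 1
        return counts

    def to_dict(self) -> dict:
        return {
            "assignments": self.assignments,
            "sequences": self.sequences,
            "junction_contrib": self.junction_contrib,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GermlineSets":
        return cls(d["assignments"], d["sequences"], d["junction_contrib"])


def sample_names(n: int) -> list[str]:
    return [f"S{i:03d}" for i in range(n)]


def emit_genotypes(panel: HaplotypePanel, config: SimConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Fold the haplotype panel into a diploid GenotypeMatrix.

    SNV dosage is the sum of the two haplotype alleles.  Each SV is
    appended as one variant row whose dosage is the diploid copy number
    (2 minus the number of deletion-carrying haplotypes).  Returns the
    matrix plus the per-haplotype SV deletion indicator array of shape
    (n_svs, 2 * n_individuals), used downstream to build germline sets.
    """
    rng = _stage_rng(config, 1)
    n = panel.n_individuals
    samples = sample_names(n)
    dosage = (panel.hap[:, 0::2] + panel.hap[:, 1::2]).astype(float)

    refs = rng.choice(list("ACGT"), size=len(panel.variants))
    alts = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in refs])
    variants = pd.DataFrame(
        {
            "id": panel.variants["id"].to_numpy(),
            "contig": config.contig,
            "pos": panel.variants["pos"].to_numpy(),
            "ref": refs,
            "alt": alts,
            "kind": "SNV",
        }
    )

    sv_del = np.zeros((len(config.svs), 2 * n), dtype=np.uint8)
    sv_rows = []
    sv_dosage = []
    for k, sv in enumerate(config.svs):
        dels = (rng.random(2 * n) < sv.deletion_freq).astype(np.uint8)
        rounds = 0
        while dels.min() == dels.max():  # keep the SV polymorphic
            rounds += 1
            if rounds > _MAX_MAF_ROUNDS:
                raise RuntimeError(f"SV {sv.id}: could not draw a polymorphic genotype")
            dels = (rng.random(2 * n) < sv.deletion_freq).astype(np.uint8)
        sv_del[k] = dels
        cn = 2 - (dels[0::2] + dels[1::2])
        sv_dosage.append(cn.astype(float))
        sv_rows.append(
            {"id": sv.id, "contig": config.contig, "pos": sv.position,
             "ref": "N", "alt": "<DEL>", "kind": "SV"}
        )

    if sv_rows:
        variants = pd.concat([variants, pd.DataFrame(sv_rows)], ignore_index=True)
        dosage = np.vstack([dosage, np.array(sv_dosage)])
        hap_full = np.vstack([panel.hap, 1 - sv_del])  # SV haplotype = retained copy
    else:
        hap_full = panel.hap

    gm = GenotypeMatrix(variants=variants, samples=samples, dosage=dosage, haplotypes=hap_full)
    return gm, sv_del


def build_germline_sets(panel: HaplotypePanel, config: SimConfig, sv_del: np.ndarray) -> GermlineSets:
    """Assign coding alleles to each haplotype gene copy.

    Haplotypes deleted by an SV carry no allele for the affected genes
    (copy number drops accordingly).  Linked alleles follow the alternate
    allele of their tag variant deterministically; all other copies draw
    from the gene's allele-frequency spectrum.
    """
    rng = _stage_rng(config, 2)
    n = panel.n_individuals
    samples = sample_names(n)
    vid_to_row = {v: i for i, v in enumerate(panel.variants["id"])}
    link_by_gene = {l.gene: l for l in config.linked_alleles}
    deleted_genes: dict[str, np.ndarray] = {}
    for k, sv in enumerate(config.svs):
        for gname in sv.genes:
            deleted_genes[gname] = sv_del[k]

    sequences = {g.name: {a.name: a.coding_seq for a in g.alleles} for g in config.genes}
    contribs = {g.name: {a.name: a.junction_aa for a in g.alleles} for g in config.genes}

    assignments: dict[str, dict[str, list[str]]] = {s: {} for s in samples}
    for g in config.genes:
        names = [a.name for a in g.alleles]
        freqs = np.asarray(g.allele_freqs, dtype=float)
        link = link_by_gene.get(g.name)
        draw = rng.choice(len(names), size=2 * n, p=freqs)
        if link is not None:
            tag = panel.hap[vid_to_row[link.variant_id]]
            linked_idx = names.index(link.allele)
            others = [i for i in range(len(names)) if i != linked_idx]
            if others:
                rest = freqs[others] / freqs[others].sum()
                alt_draw = rng.choice(others, size=2 * n, p=rest)
            else:
                alt_draw = np.full(2 * n, linked_idx)
            draw = np.where(tag == 1, linked_idx, alt_draw)
        removed = deleted_genes.get(g.name, np.zeros(2 * n, dtype=np.uint8))
        for i, s in enumerate(samples):
            copies = [names[draw[h]] for h in (2 * i, 2 * i + 1) if not removed[h]]
            if copies:
                assignments[s][g.name] = copies
    return GermlineSets(assignments=assignments, sequences=sequences, junction_contrib=contribs)


# ---------------------------------------------------------------------------
# repertoires
# ---------------------------------------------------------------------------

def gene_weights(
    config: SimConfig,
    genotypes: GenotypeMatrix,
    germline: GermlineSets,
    sample: str,
    segment: str,
) -> pd.Series:
    """Multiplicative sampling weights for one individual and segment.

    ``w_g = baseline_g * exp(sum_e beta_e * dosage(e)) * cn_g / 2``,
    normalised to sum to 1 over genes with positive weight.
    """
    col = genotypes.samples.index(sample)
    vid_to_row = {v: i for i, v in enumerate(genotypes.variants["id"])}
    weights = {}
    for g in config.genes:
        if g.segment != segment:
            continue
        cn = germline.copy_number(sample, g.name)
        w = g.baseline_weight * cn / 2.0
        for eff in config.effects:
            if eff.gene == g.name:
                w *= np.exp(eff.beta * genotypes.dosage[vid_to_row[eff.variant_id], col])
        weights[g.name] = w
    s = pd.Series(weights, dtype=float)
    total = s.sum()
    if total <= 0:
        raise RuntimeError(f"all {segment} gene weights are zero for {sample}")
    return s / total


def simulate_repertoire(
    genotypes: GenotypeMatrix,
    germline: GermlineSets,
    config: SimConfig,
) -> pd.DataFrame:
    """Draw AIRR-style rearrangement records for every individual.

    Returns a table with columns ``sample_id, v_call, j_call, junction_aa,
    v_identity, j_identity, duplicate_count``.  Unmutated records carry
    both identities at 100; mutated records have V and/or J identity drawn
    below 100.  Genes at copy number 0 never appear.
    """
    rng = _stage_rng(config, 3)
    v_genes = [g for g in config.genes if g.segment == "V"]
    j_genes = [g for g in config.genes if g.segment == "J"]
    if len(v_genes) < 2 or len(j_genes) < 2:
        raise ValueError("need at least 2 V and 2 J genes")
    vid_to_row = {v: i for i, v in enumerate(genotypes.variants["id"])}
    by_gene: dict[str, list[EffectSpec]] = {}
    for eff in config.effects:
        by_gene.setdefault(eff.gene, []).append(eff)

    def allele_tables(genes):
        """Per-gene allele-name list plus per-individual copy pair
        (indices into that list; -1 marks a missing copy)."""
        names, contribs, copies = [], [], []
        for g in genes:
            a_names = [a.name for a in g.alleles]
            names.append([f"{g.name}*{a}" for a in a_names])
            contribs.append([germline.junction_contrib[g.name][a] for a in a_names])
            pair = np.full((len(genotypes.samples), 2), -1, dtype=np.int64)
            for s_idx, s in enumerate(genotypes.samples):
                mine = germline.alleles_of(s, g.name)
                for c, a in enumerate(mine[:2]):
                    pair[s_idx, c] = a_names.index(a)
            copies.append(pair)
        return names, contribs, copies

    v_names, v_contribs, v_copies = allele_tables(v_genes)
    j_names, j_contribs, j_copies = allele_tables(j_genes)

    def weights(genes, col, sample):
        w = np.empty(len(genes))
        for gi, g in enumerate(genes):
            cn = germline.copy_number(sample, g.name)
            wg = g.baseline_weight * cn / 2.0
            for eff in by_gene.get(g.name, []):
                wg *= np.exp(eff.beta * genotypes.dosage[vid_to_row[eff.variant_id], col])
            w[gi] = wg
        if config.usage_noise_sd > 0:
            # biological inter-individual variability in gene preference
            # (mean-one lognormal); without it the compositional closure
            # of usage would make every gene respond detectably to every
            # strong planted effect
            s = config.usage_noise_sd
            w = w * rng.lognormal(-s * s / 2.0, s, size=len(genes))
        total = w.sum()
        if total <= 0:
            raise RuntimeError(f"all gene weights are zero for {sample}")
        return w / total

    sizes = np.empty(len(genotypes.samples), dtype=np.int64)
    v_idx_parts, j_idx_parts = [], []
    for col, sample in enumerate(genotypes.samples):
        if config.repertoire_size_sd > 0:
            mu = np.log(config.repertoire_size)
            sigma = config.repertoire_size_sd
            size = max(1, int(rng.lognormal(mu - sigma**2 / 2, sigma)))
        else:
            size = int(config.repertoire_size)
        sizes[col] = size
        v_counts = rng.multinomial(size, weights(v_genes, col, sample))
        v_idx_parts.append(np.repeat(np.arange(len(v_genes)), v_counts))
        j_idx_parts.append(rng.choice(len(j_genes), size=size, p=weights(j_genes, col, sample)))

    total = int(sizes.sum())
    sample_idx = np.repeat(np.arange(len(genotypes.samples)), sizes)
    v_idx = np.concatenate(v_idx_parts)
    j_idx = np.concatenate(j_idx_parts)

    def materialise(genes, names, contribs, copies, idx):
        max_alleles = max(len(n) for n in names)
        call_lut = np.empty((len(genes), max_alleles), dtype=object)
        contrib_lut = np.empty((len(genes), max_alleles), dtype=object)
        for gi in range(len(genes)):
            for ai, nm in enumerate(names[gi]):
                call_lut[gi, ai] = nm
                contrib_lut[gi, ai] = contribs[gi][ai]
        pair = np.stack(copies)  # (n_genes, n_samples, 2)
        copy_pick = rng.integers(0, 2, size=total)
        a0 = pair[idx, sample_idx, 0]
        a1 = pair[idx, sample_idx, 1]
        allele = np.where(a1 >= 0, np.where(copy_pick == 1, a1, a0), a0)
        if np.any(allele < 0):
            bad = np.flatnonzero(allele < 0)[0]
            raise RuntimeError(
                f"record drawn for gene with no germline copy "
                f"({genes[idx[bad]].name}, sample index {sample_idx[bad]})"
            )
        pair_code = idx * max_alleles + allele
        uniq, inv = np.unique(pair_code, return_inverse=True)
        calls = pd.Categorical.from_codes(inv, categories=list(call_lut.ravel()[uniq]))
        return calls, contrib_lut[idx, allele]

    v_call, v_contrib = materialise(v_genes, v_names, v_contribs, v_copies, v_idx)
    j_call, j_contrib = materialise(j_genes, j_names, j_contribs, j_copies, j_idx)

    # inserts: bucket records by insert length, build each bucket's strings
    # in one fixed-width unicode view
    ins_len = rng.poisson(config.insert_len_mean, size=total)
    inserts = np.empty(total, dtype=object)
    inserts[ins_len == 0] = ""
    for L in np.unique(ins_len[ins_len > 0]):
        rows = np.flatnonzero(ins_len == L)
        letters = rng.choice(AMINO_ACIDS, size=(len(rows), int(L)))
        inserts[rows] = letters.view(f"<U{int(L)}").ravel()
    junctions = [a + b + c for a, b, c in zip(v_contrib, inserts, j_contrib)]

    v_ident = np.full(total, 100.0)
    j_ident = np.full(total, 100.0)
    mutated = rng.random(total) < config.mutated_fraction
    which = rng.integers(0, 3, size=total)  # 0: V, 1: J, 2: both
    low = np.round(rng.uniform(90.0, 99.9, size=(2, total)), 1)
    v_ident[mutated & (which != 1)] = low[0, mutated & (which != 1)]
    j_ident[mutated & (which != 0)] = low[1, mutated & (which != 0)]

    return pd.DataFrame(
        {
            "sample_id": pd.Categorical.from_codes(sample_idx, categories=genotypes.samples),
            "v_call": v_call,
            "j_call": j_call,
            "junction_aa": junctions,
            "v_identity": v_ident,
            "j_identity": j_ident,
            "duplicate_count": 1 + rng.poisson(1.0, size=total),
        }
    )


# ---------------------------------------------------------------------------
# one-call cohort driver
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    panel: HaplotypePanel
    genotypes: GenotypeMatrix
    germline: GermlineSets
    records: pd.DataFrame
    truth: SimTruth


def simulate_cohort(config: SimConfig) -> SimResult:
    """Run all generator stages for one cohort."""
    panel = simulate_haplotypes(config)
    genotypes, sv_del = emit_genotypes(panel, config)
    germline = build_germline_sets(panel, config, sv_del)
    records = simulate_repertoire(genotypes, germline, config)
    return SimResult(config, panel, genotypes, germline, records, build_truth(config))


# ---------------------------------------------------------------------------
# study-condition configurations
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int = 15) -> str:
    # avoid stop codons so translation is clean
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in ("TAA", "TAG", "TGA"):
            codons.append(c)
    return "".join(codons)


def _mutate_cds(rng: np.random.Generator, cds: str) -> str:
    # single-nucleotide substitution avoiding stop codons
    while True:
        i = int(rng.integers(0, len(cds)))
        base = rng.choice([b for b in "ACGT" if b != cds[i]])
        out = cds[:i] + base + cds[i + 1:]
        codon = out[3 * (i // 3): 3 * (i // 3) + 3]
        if codon not in ("TAA", "TAG", "TGA"):
            return out


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """Study-condition cohort: 170 individuals, 40 genes (32 V, two
    paralog-distal V, 6 J), 500 SNVs in 10 founder blocks, 8 causal SNVs
    with per-copy effects between log 1.5 and log 2.2, one deletion SV,
    one planted allele linkage, one planted aromaticity driver, and
    5,000 unique records per repertoire."""
    rng = np.random.default_rng(seed + 977)
    blocks = [BlockSpec(20_000 + 80_000 * b, 20_000 + 80_000 * b + 60_000, 50,
                        [2, 4, 6, 8, 4, 6, 8, 4, 6, 8][b]) for b in range(10)]
    locus_span = 900_000

    genes: list[GeneSpec] = []
    v_names = [f"V{k:02d}" for k in range(1, 33)] + ["V31D", "V32D"]
    j_names = [f"J{k}" for k in range(1, 7)]
    positions = np.linspace(25_000, 860_000, len(v_names) + len(j_names)).astype(int)

    shared_pools: dict[str, list[AlleleSpec]] = {}
    for pair in (("V31", "V31D"), ("V32", "V32D")):
        cds = _random_cds(rng)
        pool = [
            AlleleSpec("01", cds, "C" + "".join(rng.choice(AMINO_ACIDS, size=7))),
            AlleleSpec("02", _mutate_cds(rng, cds), "C" + "".join(rng.choice(AMINO_ACIDS, size=7))),
        ]
        shared_pools[pair[0]] = pool
        shared_pools[pair[1]] = pool

    aromatic_pool = np.array(list("FWHY"))
    for k, name in enumerate(v_names + j_names):
        segment = "V" if name.startswith("V") else "J"
        if name in shared_pools:
            alleles = shared_pools[name]
        else:
            cds = _random_cds(rng)
            if name == "V02":  # planted aromaticity driver
                contrib = ["C" + "".join(rng.choice(aromatic_pool, size=8)) for _ in range(2)]
            elif segment == "V":
                contrib = ["C" + "".join(rng.choice(AMINO_ACIDS, size=7)) for _ in range(2)]
            else:
                contrib = ["".join(rng.choice(AMINO_ACIDS, size=3)) + "F" for _ in range(2)]
            alleles = [
                AlleleSpec("01", cds, contrib[0]),
                AlleleSpec("02", _mutate_cds(rng, cds), contrib[1]),
            ]
        genes.append(GeneSpec(name, int(positions[k]), segment, alleles, [0.7, 0.3]))

    betas = [np.log(1.5), np.log(2.0), np.log(1.8), np.log(2.2),
             np.log(1.6), np.log(2.0), np.log(1.7), np.log(1.9)]
    effects = [EffectSpec(f"b{b}v25", f"V{b + 1:02d}", betas[b]) for b in range(8)]

    cfg = SimConfig(
        n_individuals=170,
        locus_span=locus_span,
        blocks=blocks,
        genes=genes,
        paralog_pairs=[
            ParalogPairSpec("V31", "V31D", "V31ambi"),
            ParalogPairSpec("V32", "V32D", "V32ambi"),
        ],
        effects=effects,
        svs=[SVSpec("sv1", 700_500, ["V30"], 0.25)],
        linked_alleles=[LinkageSpec("V01", "02", "b0v25")],
        property_effects={"aromaticity": "b1v25"},
        repertoire_size=5000,
        mutated_fraction=0.3,
        seed=seed,
    )
    return dataclasses.replace(cfg, **overrides)


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """Default cohort with no planted effects, SVs or allele linkage —
    every association is a false positive by construction."""
    cfg = default_config(seed)
    cfg = dataclasses.replace(
        cfg, effects=[], svs=[], linked_alleles=[], property_effects={}
    )
    return dataclasses.replace(cfg, **overrides)


def clique_config(seed: int = 0, k: int = 9, **overrides) -> SimConfig:
    """Default cohort where one causal variant drives ``k`` genes, planting
    a k-gene co-regulation clique in the shared-guQTL network.

    The shared effects are balanced in both directions so the total
    sampling weight is invariant to the causal dosage: usage is
    compositional, and an unbalanced multi-gene effect would otherwise
    leak a detectable closure signal into every remaining gene.  Mixed
    effect directions also match how co-regulated gene groups behave at
    a shared variant (some genes up, others down).
    """
    cfg = default_config(seed)
    n_up = (k + 1) // 2
    n_down = k - n_up
    # n_up (f_up - 1) + n_down (f_down - 1) = 0 balances the heterozygote
    # weight sum exactly; the homozygote sum cannot be balanced too (for a
    # multiplicative model sum f = sum f^2 = k forces f = 1), so f_up is
    # kept moderate to make the residual quadratic closure term small
    # against the biological usage noise while each driven gene stays far
    # above the significance threshold
    f_up = 1.35
    f_down = 1.0 - n_up * (f_up - 1.0) / n_down
    if f_down <= 0:
        raise ValueError("cannot balance clique effects for this k")
    shared = [
        EffectSpec("b0v25", f"V{i + 1:02d}",
                   float(np.log(f_up if i < n_up else f_down)))
        for i in range(k)
    ]
    solo = [EffectSpec(f"b{b}v25", f"V{b + 15:02d}", float(np.log(1.8)))
            for b in range(4, 8)]
    cfg = dataclasses.replace(cfg, effects=shared + solo, linked_alleles=[],
                              property_effects={})
    return dataclasses.replace(cfg, **overrides)
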