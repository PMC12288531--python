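# Methods

`igqtl` maps *gene-usage QTLs* (guQTLs) in immunoglobulin light-chain
loci: germline variants whose genotype associates with how often a V or
J gene appears in the expressed antibody repertoire. It implements the
analysis layer that sits downstream of repertoire alignment and
assembly-based genotyping, plus a cohort simulator that plants known
effects so every stage can be validated by recovery.

## Repertoire processing and usage

Input is an AIRR rearrangement table of unique BCRs (one row per unique
sequence; `duplicate_count` is carried but never used in frequencies).
Records partition into an **unmutated** set — V *and* J identity to the
assigned germline allele equal to 100%, enriching for antigen-naive
cells — and a **mutated** set (any mismatch). All analyses default to
the unmutated partition.

IGK-style proximal/distal gene duplicates can be indistinguishable at
the allele level. A paralog pair is collapsed to a single ambiguous
("ambi") label for an individual unless that individual's germline
allele sets for the two genes are disjoint, in which case the specific
labels are kept. In the usage matrix the non-evaluable side of this
split is stored as missing (NaN), not zero, so association tests drop
those individuals pairwise: a structural zero would otherwise mimic a
biological absence.

Usage of gene *g* in sample *s* is the fraction of unique records of
*s* calling *g*. Samples with fewer than 100 unique records are
excluded; genes need a count of at least 10 in at least one retained
sample. Frequencies are computed before the gene filter, so dropped
genes still contribute to the denominator and per-sample frequencies
sum to 1 over all genes observed in the partition.

## CDR3 physicochemical properties

The CDR3 is the junction minus its conserved anchor residues. Nine
descriptors are computed per sequence and averaged per sample
(unweighted over unique records): length, GRAVY (mean Kyte–Doolittle
hydropathy), aromaticity (fraction of F/W/H/Y — the alakazam
convention, which includes histidine), aliphatic index on the
mole-fraction scale (X_A + 2.9·X_V + 3.9·(X_I + X_L)), acidity (D/E
fraction), basicity (R/H/K fraction), net side-chain charge at pH 7.4
(Henderson–Hasselbalch with the EMBOSS pK set {C 8.5, D 3.9, E 4.1,
H 6.5, K 10.8, R 12.5, Y 10.1}; termini excluded, not normalised by
length), mean Grantham polarity, and mean Zimmerman bulkiness. Scale
tables ship as a versioned JSON data file. Sequences containing
ambiguity codes (e.g. `X`) are excluded from sample means and counted,
not zero-filled. Whether "length" refers to the junction or the CDR3 is
a convention choice; the CDR3 is used here.

## Association model

Genotypes are additive dosages in {0,1,2}: alternate-allele counts for
SNVs, diploid copy number for deletion SVs (copy number behaves
additively on usage, so the same encoding serves both). Variants are
filtered to cohort MAF ≥ 0.05 (inclusive) and ≤ 10% missingness;
missing dosages are dropped pairwise per test.

Each trait (usage frequency or property mean) is regressed on dosage by
ordinary least squares with an intercept; the slope's two-sided t-test
gives the p-value and the adjusted R² is reported. Usage is analysed
untransformed. No covariates are included by default (the model admits
none; a hook exists). Variants in complete LD (genotype r² = 1 within
1e-12, a transitive relation, so classes are connected components)
collapse to one class represented by the lowest-position member; the
Bonferroni threshold is 0.05 / (number of classes), shared by all genes
of a locus/partition. The per-gene lead is the significant class with
the smallest p, ties broken by genomic position then id. Fold change is
the ratio of the larger homozygote-group mean to the smaller; an empty
homozygote group makes it undefined (no heterozygote fallback), and a
zero smaller mean is reported as an infinite sentinel.

Region annotation assigns each variant (1-based) to BED features
(0-based half-open) with priority RSS > V-exon > L-Part1 > intron,
defaulting to intergenic. Enrichment of QTL variants in an interval set
(e.g. TFBS clusters) uses a one-sided Fisher exact test on the 2×2
table of QTL status × interval membership, with a 0.5 continuity
correction on the odds ratio when a cell is empty.

## LD and haplotype blocks

Pairwise r² is the squared Pearson correlation of dosages (the
`--geno-r2` convention). D′ is estimated from two-locus haplotype
frequencies: counted directly when phase is available, otherwise by EM
over the double-heterozygote ambiguity (tolerance 1e-8, ≤ 1000
iterations). The 95% CI on |D′| comes from a profile likelihood over a
grid of D′ ∈ [0,1] in steps of 0.001 with allele frequencies fixed at
their sample values, cutting 5% from each tail of the normalised
likelihood (the Haploview approach; deterministic, unlike a bootstrap).
Phased data use the exact multinomial haplotype-count likelihood;
unphased data the 3×3 genotype likelihood under random mating.

Blocks follow Gabriel-style rules with the published defaults, all
config-exposed: a pair is strong LD iff CI-low ≥ 0.70 and CI-high ≥
0.98; recombination iff CI-high < 0.90; otherwise uninformative. A
candidate interval qualifies as a block when it contains at least one
informative pair and ≥ 95% of its informative pairs are strong LD;
non-overlapping blocks are then chosen greedily by bp span (largest
first, ties leftmost). Gene/block overlap requires ≥ 1 bp in a shared
0-based half-open coordinate frame.

## Networks and allele linkage

Each gene's guQTL set is the union of all member variants of its
significant classes (variant level, not class level). Genes sharing at
least one variant are joined by an edge weighted by the Jaccard index;
the graph's connected components and all maximal cliques of size ≥ 2
(Bron–Kerbosch with pivoting, via networkx) summarise co-regulation
structure with deterministic ordering. Force-directed layout is a
presentation-only export hook.

For each gene with a lead guQTL, coding-allele copies (two per
individual, fewer under deletion) are tabulated against the three
lead-variant genotype groups. Copy counting (rather than individual
carriage) keeps margins stable; carriage percentages are a display
concern. Genes whose major allele exceeds 95% cohort frequency are
flagged as lacking allelic variation and excluded from testing (and
from the Bonferroni denominator, which is the number of genes actually
tested). The 2×2 test is the exact two-sided hypergeometric
(point-probability method). Larger tables use the exact Freeman–Halton
sum when enumeration of all margin-preserving tables fits a node budget
(default 2e6); beyond that, a seeded Monte Carlo over Patefield-sampled
tables (1e5 draws) is used and the estimator's standard error reported.
Allele differences are flagged missense/nonsense by translating coding
sequences and comparing proteins; synonymous-only pairs can optionally
be merged (distinct by default).

## The simulator

The generator emulates a cohort of ~170 individuals genotyped across a
single light-chain-like locus with matched repertoires.

**Haplotypes.** The locus is tiled by non-overlapping blocks; each
block carries 2–8 founder haplotypes, and every individual haplotype
copies one founder per block, chosen independently across blocks. This
produces D′ = 1 within blocks and ≈ 0 between them — the simplest
generator for block-structured LD, with block length and founder count
as the only dials. Variant columns whose realised cohort MAF falls
below the floor (0.05) are resampled at the founder level (bounded
rounds, then an error). Variants referenced by effect or allele-tag
specs get balanced founder patterns (half of founders carry the
alternate allele) so planted signals sit at intermediate frequency and
both homozygote groups exist.

**Usage model.** Individual *i* samples V gene *g* with weight
`baseline_g · exp(Σ_e β_e · dosage_i(e)) · cn_g(i)/2 · ε_{ig}` where
`ε_{ig}` is mean-one lognormal noise (σ = 0.3 by default) representing
biological inter-individual variability in gene preference. The noise
term matters: usage frequencies are compositional, and with only
multinomial counting noise the closure of frequencies would make every
gene respond detectably to any strong planted effect — real cohorts do
not behave that way because inter-individual variance dominates (gene
usage heritability estimates, i.e. variance explained by a lead
variant, are well below 1). Records are drawn multinomially (5,000
unique records per sample by default; depth can be made lognormal).

**Study conditions.** The default configuration fixes 170 individuals;
40 genes (32 V plus two paralog-distal V genes sharing allele pools,
and 6 J); 500 SNVs in 10 blocks of 50; 8 causal SNVs, one per block,
with per-copy effects between log 1.5 and log 2.2; one deletion SV
(frequency 0.25) removing a V gene; one coding allele tagged perfectly
to a causal variant; and one causal variant whose target V gene carries
an aromatic-rich germline junction, planting a CDR3-aromaticity QTL.
Effects are capped at log 2.2 because renormalisation biases the
realised homozygote fold change by roughly (1 + (fold − 1)/n_genes);
at fold e^{2·log 2.2} ≈ 4.8 that bias is ~10%, small against the ±20%
recovery band used in validation.

**Planted clique.** A separate configuration plants one variant driving
nine genes. The effects are split between directions and sized so the
heterozygote weight sum is unchanged (n_up(f_up−1) + n_down(f_down−1) =
0, with f_up = 1.35). Exact closure cancellation at both heterozygotes
and homozygotes is impossible for a multiplicative model (Σf = Σf² = k
forces f = 1), so a small quadratic residual remains; at these factors
its regression non-centrality is ≈ 0.5, far below the Bonferroni
threshold, while each driven gene keeps |t| ≈ 9. Mixed effect
directions also reflect how co-regulated gene groups behave at a shared
variant.

**Junctions.** junction = germline 3′ V contribution + uniform random
insert (Poisson length, mean 3) + germline 5′ J contribution, so
germline-encoded residues are constant per V/J allele pair. Somatic
hypermutation is represented only by identity flags (mutated records
draw V and/or J identity uniformly in [90, 99.9]); the pipeline
consumes identities, not alignments. No read-level artefacts, UMIs,
clonal structure or heavy-chain pairing are simulated — recovery
results validate the statistical machinery on idealised repertoires,
not robustness to upstream processing noise.

## Validation sizes and determinism

All randomness flows through `numpy.random.default_rng` seeded from the
configuration, and identical configurations reproduce byte-identical
outputs. The test suite validates: causal-variant lead recovery and
fold-change accuracy over 20 cohorts at the study conditions;
family-wise false-positive control over 20 null cohorts (no effects, no
SVs — an SV is a true mechanical effect, so the null excludes it);
exact planted-block recovery over 50 two-founder loci plus agreement of
the interval scan with brute-force enumeration on 200 random instances
(≤ 12 variants); exact-test oracles (2×2 golden value 34/70,
exact-vs-Monte-Carlo agreement, hypergeometric tails); property-QTL
recovery over 20 cohorts; KS uniformity of 10,000 null regression
p-values at n = 170; and planted 9-gene clique recovery over 10 cohorts
plus Bron–Kerbosch agreement with exhaustive enumeration on 200 random
graphs (≤ 15 nodes). `scripts/acceptance.py` recomputes the same
quantities with 8 cohort replicates per quantity, a size chosen to keep
a reproduction run short while leaving the proportions stable.

## Known limitations

* The D′ CI uses the profile-likelihood grid; other tools' CI internals
  (e.g. LDBlockShow) may differ at the margins even under the same
  Gabriel rule set.
* The exact r×c Fisher test enumerates tables; for large totals with
  several rows it falls back to Monte Carlo rather than implementing
  the full network algorithm.
* Trans effects, conditional/secondary QTLs, covariates and mixed
  models are out of scope; the covariate hook defaults to none.
* The simulator's noise model (lognormal gene preference) is a
  single-parameter stand-in for the many sources of real biological
  variability; passing recovery tests demonstrates correctness of the
  estimators under the stated model, not performance on any particular
  real cohort.
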