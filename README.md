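# igqtl

Gene-usage QTL mapping for immunoglobulin light-chain loci.

Antibody light chains are assembled by V(D)J recombination from the IGK
and IGL loci, and individuals differ heritably in how often each V and
J gene appears in their expressed repertoire. `igqtl` tests whether
germline variants — SNVs and gene copy-number structural variants — in
*cis* explain that variation. It is aimed at immunogenomics groups who
have (i) AIRR-seq rearrangement tables with personalized germline
allele assignments, (ii) a multi-sample VCF of common variants across
the locus, and (iii) per-individual germline allele sets, and who want
the downstream statistics as a tested, reproducible pipeline.

## What it computes

For gene *g* with usage frequency `u_gs` in sample *s* (fraction of
unique unmutated BCRs calling *g*) and additive dosage `d_vs` at
variant *v* (alternate-allele count, or diploid copy number for
deletion SVs):

    u_gs = α + β d_vs + ε,     ε ~ iid

fit by OLS; the slope's two-sided t-test gives P, with adjusted R² and
the fold change between homozygote group means reported. Variants in
complete LD (genotype r² = 1) count as one test; significance is
Bonferroni at α = 0.05 over the effective test count, and the smallest-P
significant class per gene is its *lead guQTL*. Around this core the
package provides:

* unmutated/mutated repertoire partitioning, paralog "ambi" collapsing
  with per-individual disambiguation, and filtered usage matrices;
* nine CDR3 physicochemical properties (length, GRAVY, aromaticity,
  aliphatic index, acidity, basicity, charge at pH 7.4, polarity,
  bulkiness) and property-QTL mapping on per-sample means;
* pairwise r²/D′ with profile-likelihood confidence intervals and
  Gabriel-style haplotype block calling, plus block/gene overlap and
  block-size composition;
* gene networks from shared guQTL variants (Jaccard edges, connected
  components, maximal cliques via Bron–Kerbosch);
* Fisher exact tests (exact 2×2 and r×c with Monte-Carlo fallback)
  linking coding-allele carriage to lead-guQTL genotypes, and one-sided
  Fisher enrichment of guQTLs in annotation intervals;
* a cohort simulator with founder-block LD, planted additive usage
  effects, copy-number SVs, allele–variant linkage and CDR3-composition
  effects, emitting VCF / AIRR TSV / germline JSON plus a truth table.

See `docs/methods.md` for the model details and design choices.

## Worked example

Simulate a study-condition cohort (170 individuals, 40 genes, 500 SNVs
in 10 LD blocks, 8 planted causal variants, 5,000 unique BCRs per
sample) and map guQTLs:

```python
from igqtl.simulate import default_config, simulate_cohort
from igqtl.evaluation import analyse, causal_lead_recovery

sim = simulate_cohort(default_config(seed=7))
ana = analyse(sim)                       # usage -> MAF filter -> LD classes -> OLS scan
leads = ana.guqtl[ana.guqtl["lead"]]
print(leads[["gene", "class_rep", "beta", "p_value", "adjusted_r2", "fold_change"]])
print(causal_lead_recovery(ana, sim))
```

Output (abridged to the eight planted genes):

```
gene class_rep    beta      p_value  adjusted_r2  fold_change
 V01      b0v0  0.0139 1.798590e-20        0.398         2.21
 V02      b1v3 -0.0319 8.385690e-45        0.690         3.37
 V03     b2v25  0.0257 2.037937e-40        0.651         3.20
 V04     b3v25  0.0426 1.401099e-41        0.661         4.30
 ...

variant gene  lead_recovered  fold_change  planted_fold  fold_rel_err
  b0v25  V01            True         2.21          2.25         0.018
  b1v25  V02            True         3.37          4.00         0.158
  b2v25  V03            True         3.20          3.24         0.014
  b3v25  V04            True         4.30          4.84         0.112
  ...
```

Reading this: 224 effective variant classes give a Bonferroni threshold
of 2.2e-4; every planted causal variant is recovered inside the lead
class of its target gene (`b0v0` and `b0v25` share a two-founder block,
hence one class); the measured homozygote fold changes track the
planted `exp(2β)` within the sampling and renormalisation error of a
compositional trait; and the lead guQTLs explain 40–69% of usage
variance, with the rest being the simulated biological noise.

The same stages run from the shell on files:

```sh
igqtl run --seed 7 --out-dir out/                 # simulate + full pipeline
igqtl guqtl --vcf out/cohort.vcf --usage out/usage_v_unmutated.tsv --out guqtl.tsv
igqtl ldblocks --vcf out/cohort.vcf --out blocks.tsv
```

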