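# heteroseq

Analysis toolkit for hybrid-crop heterosis transcriptomics: given
gene-level RNA-seq counts for two inbred parents and their F1 hybrid
(plus phased parental SNPs for the hybrid), it answers the questions a
heterosis study asks of expression data —

* which genes are **differentially expressed** between the hybrid and
  its parents (negative-binomial Wald test, median-of-ratios
  normalization, BH-FDR);
* what **inheritance mode** each hybrid-vs-parent DEG shows
  (additive / partial dominance / dominance / over-dominance), via the
  Hp statistic;
* which genes show **allele-specific expression** (ASE) in the hybrid,
  and whether the biased parent is the same in different tissues;
* whether ASE genes **overlap parental DEGs** and **carry more
  variants** than the genomic background;
* which annotation **terms are over-represented** in any gene set.

It ships a synthetic-data generator that plants every one of these
signals with known ground truth, so the whole pipeline is testable on a
laptop with no sequencing data.  Intended users are plant-genomics
groups analysing parent/hybrid trios and methods people who want a
small, fully specified reference implementation of these classic
computations.

## The statistics

**Active genes.** A gene is actively expressed in a sample group when it
has ≥ 2 reads in ≥ 2 biological replicates.

**Differential expression.** Counts K_ij are modelled as
NB(s_j · q_ij, α_i) with Var = μ + α μ². Size factors s_j are
median-of-ratios; dispersions α_i are method-of-moments estimates shrunk
50/50 toward a fitted mean–dispersion trend α(μ) = a₀/μ + a₁. A
two-group log-link GLM is fit per gene by IRLS with log s_j offsets; the
Wald statistic β̂/SE(β̂) gives a two-sided normal p, BH-adjusted per
contrast. DEG ⇔ FDR ≤ 0.01 and |log2FC| ≥ 1.

**Inheritance mode (Hp).** With mean normalized expression p1 (mother),
p2 (father), f1 (hybrid): a = |p1 − p2|/2, d = f1 − (p1 + p2)/2,
Hp = d/a. Categories: additive (−0.2 < Hp ≤ 0.2), partial dominance
(−0.8 < Hp ≤ −0.2 or 0.2 < Hp ≤ 0.8), dominance (−1.2 < Hp ≤ −0.8 or
0.8 < Hp ≤ 1.2), over-dominance (Hp ≤ −1.2 or Hp > 1.2).

**ASE.** Informative SNPs (homozygous-different between parents) assign
hybrid reads to a parental haplotype; gene-level maternal/paternal
counts are tested with an NB GLM (replicate + allele factors, Wald test
on the allele coefficient). ASEG ⇔ BH-adjusted p ≤ 0.05. Genes ASEG in
both tissues are consistent-maternal, consistent-paternal, or
shift-direction.

**Set statistics.** Overlap enrichment resamples both sets from the
universe (default 1000 rounds) and reports a one-sample t-test against
the observed overlap plus the empirical p = (1 + #{null ≥ obs})/(n+1).
Term over-representation is the upper-tail hypergeometric test with
BH adjustment. ASEG variant density uses gene-set permutation.

**Variants.** Records are hard-filtered (SNPs: QUAL < 30, QD < 2,
SOR > 3, FS > 60, MQ < 40, MQRankSum < −12.5, ReadPosRankSum < −8;
indels: QUAL < 30, QD < 2, FS > 200, MQ < 40, ReadPosRankSum < −20) and
classified against gene models into consequence terms mapped to
HIGH / MODERATE / LOW / MODIFIER impact tiers.

## Worked example

```python
import heteroseq as h

cfg = h.SimConfig(seed=1, n_genes=1000)
cm, truth = h.simdata.simulate_trio_counts(cfg)
sf = h.diffexpr.size_factors(cm)
de_m = h.diffexpr.nb_wald_test(cm, cm.sample_ids(role="maternal", tissue="leaf"),
                               cm.sample_ids(role="hybrid", tissue="leaf"), sf=sf)
de_p = h.diffexpr.nb_wald_test(cm, cm.sample_ids(role="paternal", tissue="leaf"),
                               cm.sample_ids(role="hybrid", tissue="leaf"), sf=sf)
table, pct = h.dominance.classify_dghp(cm, de_m, de_p, "leaf", size_factors=sf)
print(len(table)); print(pct.round(2))
```

prints

```
299
category
over_dominance       84.62
dominance             5.69
partial_dominance     7.02
additive              2.68
```

— 299 genes are DEGs against at least one parent in leaf, and ~85% of
them are over-dominant (the hybrid lies outside the parental range),
the hallmark pattern of hybrid-rice expression heterosis. The
`examples/` directory has one short script per capability
(`python examples/01_simulate_and_differential_expression.py`, …), each
printing its results with a line on what they mean.

The same pipeline runs from a shell:

```sh
heteroseq all --config examples/pipeline_config.yaml
```

which simulates a trio, runs every stage in dependency order and writes
one TSV per result plus a run report; reruns with the same seed are
byte-identical.

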