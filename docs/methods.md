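# Methods

This note records the models behind each heteroseq component, the
parameters that matter, and the choices made where the design was
genuinely open.

## Study design and data model

The unit of analysis is a **trio**: an inbred maternal line, an inbred
paternal line, and their F1 hybrid, profiled by bulk RNA-seq in one or
more tissues with ≥ 2 biological replicates per accession/tissue
(defaults: 2 tissues × 3 replicates, the design of the hybrid-rice
studies this package serves). The package analyses one trio at a time;
multi-hybrid designs (e.g. two hybrids sharing a father) are handled by
running per trio, which loses nothing because every statistic here is
defined within a trio.

Counts are modelled as negative binomial with Var = μ + αμ² — the
quadratic parameterization in which α is the squared biological
coefficient of variation at high depth. α is shared across samples of a
gene but not across genes.

## Normalization and dispersion

Size factors are median-of-ratios: with reference genes R = genes
nonzero in every sample, s_j = median_{i∈R} K_ij / (∏_j K_ij)^{1/m}.
They are defined up to a common constant; only ratios matter.

Per-gene dispersion is method of moments on normalized counts,
α̂_raw = max(0, (s² − μ̄)/μ̄²) computed within each replicate group and
pooled with degrees-of-freedom weights, then shrunk 50/50 toward a
least-squares trend α(μ) = a₀/μ + a₁ over genes. The 0.5 shrink weight
is the simplest stabilizer and is exposed as a parameter. At 3
replicates per group the raw estimate is very noisy; the residual
estimator noise makes the downstream Wald test mildly liberal (measured
raw type-I ≈ 0.065–0.07 at nominal 0.05 under a 3v3 null with α = 0.1;
with the true α plugged in the test is calibrated at ≈ 0.05). All-zero
genes have undefined dispersion and are reported untested (p = NA).

## Differential expression

Per gene, a two-group log-link NB GLM with log size-factor offsets is
fit by IRLS, vectorised across genes (expected-information weights
w = μ/(1+αμ); ≤ 100 iterations, ‖Δβ‖∞ < 1e-10; η clipped at ±50 so
all-zero groups stay finite). The group coefficient gives
log2FC = β̂₁/ln 2, the Wald statistic β̂₁/SE, a two-sided normal p, and
BH adjustment within each contrast. DEG ⇔ FDR ≤ 0.01 ∧ |log2FC| ≥ 1.

Deliberately omitted refinements of the reference NB-DE tools: no LFC
shrinkage, no outlier refitting (Cook's distances), no independent
filtering. These change borderline calls only and are documented as
differences, not re-implemented. There are no pseudocounts in testing;
a +0.5-pseudocount fold change is available for reporting only.

Two properties worth knowing:

* **Label swap** negates log2FC and preserves p (to numerical noise).
* **Per-sample scaling** (multiplying one sample's counts by c) is
  absorbed by the size factors, so normalized counts, base means and
  dispersions are exactly unchanged (up to one global constant); the
  GLM coefficients themselves shift slightly (the score equations
  reweight), so only well-separated calls are guaranteed stable. This
  is a property of any offset-GLM formulation, not of this
  implementation.

Sample correlations (R² of log2(normalized+1)) are computed per pair
over genes detected (raw count ≥ 1) in at least one of the two samples
— per-sample detection cannot use the replicate-based activity rule.

## Inheritance mode (Hp)

a = |p1 − p2|/2, d = f1 − (p1+p2)/2, Hp = d/a, with p1/p2/f1 the
arithmetic means of size-factor-normalized counts across replicates
within the tissue (means are the natural summary consistent with the
mid-parent formula). Interval boundaries are half-open exactly as
listed in the README, including the asymmetric over-dominance pair
(closed at −1.2, open at 1.2); they are implemented verbatim, not
symmetrized. Degenerate cases: a = 0 with d ≠ 0 gives Hp = ±∞ →
over-dominance (the hybrid differs from two identical parents — the
literal over-dominance situation); a = d = 0 gives Hp = 0 → additive.

The DGhp set is the union of the two hybrid-vs-parent DEG sets by
default (intersection available); union maximizes coverage of genes
with any hybrid-parent difference.

## Allele-specific expression

Input is per-SNP parental-allele counts (read-level phasing, mapping
bias correction and uniqueness filters are upstream concerns and out of
scope). Gene-level maternal/paternal counts are sums over informative
SNPs in a gene's exons; SNPs shared by overlapping genes count for each
and are flagged; alleles matching neither parent go to a QC tally.

The imbalance test is an NB GLM on the 2×r counts of a gene/tissue with
design intercept + replicate factor + allele factor; the replicate
factor keeps replicate-level depth differences from masquerading as
imbalance. Dispersion is per-gene MOM on within-allele replicate
variation, floored at 1e-8. Genes with summed allelic depth < 10 are
reported untested — without a floor, depth-1 genes produce degenerate
fits; the value 10 is the smallest round number at which the GLM is
consistently well-behaved. ASEG ⇔ BH-adjusted p ≤ 0.05 within tissue;
direction is the allele with the larger summed count. Cross-tissue
patterns are defined only for genes significant in both tissues.

## Overlap, enrichment, variant density

The overlap test draws |A| and |B| genes without replacement from the
declared universe (choose it deliberately — all genes with expression
data is the default) n_sim = 1000 times. Both a one-sample t-test of
the null draws against the observed overlap and the empirical
p = (1 + #{null ≥ obs})/(n_sim + 1) are reported. The t-test against a
resampled null is fragile (it treats Monte-Carlo draws as data), so the
empirical p is the recommended headline; the t version is kept because
it is the field's customary report.

Term over-representation is the exact upper-tail hypergeometric
probability with BH across terms; no ontology-graph propagation or term
de-duplication is attempted.

Variant density compares, per impact class, the variant count on ASEGs
with counts on |ASEG|-sized gene sets permuted from all genes
(n_sim = 1000) — a permutation test avoids assuming variants are
unclustered, which they are not.

## Variant filtering and effects

Hard filters follow the GATK convention. The rank-sum thresholds are
applied as MQRankSum < −12.5 and ReadPosRankSum < −8 (SNPs) / −20
(indels): rank-sum statistics are centred at zero, and positive
thresholds would discard essentially all variants; the sign fix is a
flag (`rank_sum_sign_fix`) so the verbatim positive bounds can be
applied if wanted. Missing metrics skip their criterion.

Effect classification reports one consequence per variant — the most
severe over all overlapping gene features, HIGH > MODERATE > LOW >
MODIFIER with ties broken by a fixed consequence order. Coding SNPs are
resolved by codon translation on the correct strand (CDS phase
honoured); CDS indels are frameshift iff |Δlen| mod 3 ≠ 0; splice sites
are the first/last 2 intronic bases; upstream/downstream windows are
5 kb; UTR is a single term. Genes whose CDS length fails the
divisible-by-3 check are excluded from coding calls (their variants
fall back to the non-coding context). This is a minimal, documented
subset of the standard effect-annotation ontologies — no multi-isoform
effects, MNVs, or regulatory annotations.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with planted truth written to a separate table the pipeline never
reads.

* **Counts**: baseline means lognormal (default location log 200,
  scale 1.0 — chosen for test power at bulk RNA-seq-like depths, not
  fidelity to any particular library); NB noise with α = 0.05 by
  default (a typical bulk replicate CV of ~22%). Genes planted in an
  Hp category get parent means at ratio 2^(lfc+1) (= 4 by default) and
  a hybrid mean placed at Hp targets 0, ±0.5, ±1.0, +2.5/−1.6 — all at
  least 0.1 inside their interval so noiseless classification is
  unambiguous, with the hybrid ≥ 2^lfc-fold from one parent in every
  category (the −1.6 over-dominance target is capped by f1 ≥ 0). The
  default category mix (85% over-dominant, 5% each otherwise) mirrors
  the observed predominance of over-dominance among hybrid-rice DEGs.
* **Allelic counts**: total depth Poisson(100) per gene/replicate;
  maternal counts binomial with π = fold/(1+fold) (default fold 4 →
  π = 0.8), 0.5 for balanced genes.
* **Genome/variants**: genes of identical structure (30 bp UTRs, 120+180
  bp CDS split by a 100 bp intron) on "chrSim" chromosomes with ≥ 1 kb
  gaps, strand random, CDS built from codons chosen so that every
  impact class is realizable by a designed edit (TGG→TGA stop gains,
  2-bp CDS deletions, CTG→ATG missense, GGA→GGG synonymous, intronic
  SNPs). Genes with planted ASE carry 3× the background variant rate
  (default 2 per gene) — the density enrichment the analysis should
  detect.
* **Term maps**: random term memberships plus one term drawn from
  planted DEGs.

What the generator does **not** emulate: read-level artifacts (mapping
bias, positional coverage, duplicates), SNP linkage within genes,
per-gene dispersion variation, correlated ASE and DE status, or real
genome annotation complexity (multi-isoform genes, overlapping loci).
Passing tests therefore demonstrate correctness of the computations
under the stated models, not robustness to alignment-level artifacts.

Determinism: every simulator draws from its own `default_rng([seed,
stream])`, so identical configs give byte-identical fixture files and
toggling one pipeline stage never perturbs another's stream.

## Problem sizes and numerics

The test-suite simulations use 1–5k genes, 3 replicates, depths of
100–200 — sizes at which every calibration quantity is estimated to
within ~±0.5 percentage points and the whole suite runs in well under a
minute. IRLS tolerances are listed above; BH is taken from statsmodels;
hypergeometric tails from scipy. Exact-null instances (literally equal
group counts) are snapped to log2FC = 0, p = 1 rather than left at
iteration noise below 1e-12.

## Known limitations

* Dominance classification inherits the ratio statistic's noise
  sensitivity when the additive effect a is small; errors concentrate
  next to interval boundaries (measured ~93% planted-category recovery
  at depth 200, α = 0.05, 3 replicates, vs 100% noiseless).
* The Wald tests are asymptotic; with 2–3 replicates they run mildly
  liberal (see Normalization and dispersion above). A likelihood-ratio
  or exact test would be better at these sizes but is not what the
  surrounding literature reports.
* One consequence per variant means a variant in two genes' features is
  counted once, for the more severely hit gene.
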