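# Methods

`maculaseq` implements the computational stages of a bulk RNA-seq analysis of
age-related macular degeneration (AMD): differential gene expression between
disease stages (normal, intermediate AMD, neovascular AMD) within a tissue
(macular RPE/choroid or macular neural retina), exon-level differential
splicing, per-individual allele-specific expression (ASE) at AMD risk SNPs,
marker-panel dissection QC, and the integration logic that combines these
results. Because the motivating data are restricted human donor tissue, the
package ships a synthetic-data generator whose outputs have the statistical
structure the analysis assumes, with ground-truth tables, so every stage is
testable end to end.

## Gene models

Transcript models are read from UCSC refFlat tables (0-based half-open
coordinates, preserved internally; SNP positions are 1-based, converted only
at I/O boundaries). All transcripts sharing a gene symbol are merged into a
"composite gene": the interval union of their exons defines the exon counting
bins and the exonic length used for FPKM. Merging keys on the refFlat
geneName column; identical symbols on different chromosomes are split into
per-chromosome genes, and strand conflicts resolve to the majority strand
with a warning (counting is strand-agnostic).

## Differential expression

The two-group test is a transparent negative-binomial (NB) Wald test:

* **Normalization.** Median-of-ratios size factors (default): for genes
  nonzero in every sample, factor_j = median_g count_{gj} / geomean_g.
  TMM is available as an alternative (30% trim on M-values, 5% on A-values,
  inverse-asymptotic-variance weights, reference = sample with count sum
  closest to the median).
* **Dispersion.** Per-gene method-of-moments, var = mu + alpha mu^2, pooled
  within groups with (n_g - 1) weights and floored at 1e-8. The Poisson
  component subtracted is mu * mean(1/sf) so the estimator stays centred when
  library sizes differ.
* **Test.** log2fc = log2((mu_A + 0.5) / (mu_B + 0.5)); the pseudo-mean 0.5
  bounds the fold change when a group is all zero. The standard error comes
  from the delta method under NB sampling of each group mean; the Wald
  statistic is referred to the standard normal, two-sided. BH correction is
  applied once, to raw p-values, across all tested genes.
* **Significance rule.** padj < 0.05 and |fold change| >= 1.5 in either
  direction.

This is a documented stand-in for a production shrinkage-based DE tool:
there is no dispersion shrinkage, independent filtering or outlier
refitting, and numeric equality with such tools is not a goal. The
acceptance surface is calibration (raw-p type-I rate near 0.05 on null
simulations at n = 10/group) and recovery of planted log2 fold changes. At
these sample sizes the plug-in Wald test is expected to be mildly
anticonservative (observed type-I around 0.055-0.065 at nominal 0.05);
genes that cannot be tested (all-zero in both groups) are reported in a
sidecar exclusions table, never silently dropped. One wording ambiguity was
resolved deliberately: correction is applied once to raw p-values, not
iterated on already-adjusted values.

## Differential splicing

Replicate counts are summed within each condition ("merged replica counts").
Exons need >= 10 merged counts in **both** conditions to enter the test
(boundary inclusive; the threshold is read as per-condition merged totals,
since a replicate-level reading would contradict merging). Genes with fewer
than two eligible exons are untestable (df = K - 1 >= 1 required) and are
reported as such rather than assigned p = 1. The K x 2 exons-by-conditions
table is tested with a Pearson chi-square (no continuity correction); the
contingency reading — exons against conditions — is one of two possible
interpretations of the original description and is documented here as the
adopted one. Bonferroni correction uses the number of testable genes in the
comparison (per-comparison, not global — also a documented choice).

The reported splice signal is the exon maximising |log2(prop_A / prop_B)|
over within-gene proportions, ties breaking to the lowest genomic exon
index. Significance requires Bonferroni p < 0.05 and fold change >= 1.5 at
that exon (the same fold-change cutoff as expression, the only stated
threshold). Because proportions are scale-free, a pure expression change
leaves every ratio at zero — planted-effect tests verify this orthogonality.
Per-exon ratios can be written as bedGraph tracks with one constant segment
per merged exon; true per-base coverage would need alignments, which are out
of scope.

Note that pooling replicates before a multinomial chi-square ignores
biological overdispersion between replicates, which can make the raw test
anticonservative on highly variable genes; the Bonferroni correction and the
fold-change requirement absorb this in practice (null simulations show <1%
of genes called), but the limitation is inherent to the pooled design.

## Allele-specific expression

For each (individual, SNP) record: keep confirmed heterozygotes whose
genotype alleles match the record's ref/alt; require >= 10 informative reads
(the inclusive Methods-style reading of the depth rule is used where a table
caption elsewhere says "more than 10"); test the allele split with an exact
two-sided binomial test against 0.5. The default two-sidedness is the
minimum-likelihood convention (sum of all outcome probabilities no larger
than the observed one, which under p0 = 0.5 reduces exactly to the two
symmetric tails); tail-doubling is available behind a flag.

Monoallelic records (minor-allele reads exactly 0 — the only operationally
sharp definition) remain in the tested set only when an LD proxy with
r^2 >= 0.8 confirms heterozygosity in the same individual; otherwise the
record is excluded with a machine-readable reason, since a genotyping error
is indistinguishable from true silencing at the target SNP alone.

BH correction is applied within a configurable family — default all tested
records of one tissue jointly (matching the per-tissue presentation of the
summary tables), alternatives per (tissue, SNP) or global. Summaries render
"k/n" per SNP x tissue x disease group: significant over tested
heterozygotes, with "0/0" marking cells with no testable heterozygote.

## Marker-panel QC

Panel fractions are 100 x panel-count sum / library sum per sample. The
bundled panels: 14 retinal phototransduction genes (GNGT1 ... SLC24A1) and 3
RPE/choroid genes (BEST1, RDH5, RPE65). A sample is flagged when the
opposite tissue's panel takes strictly more than 1% of its reads; the rule
is applied symmetrically to both tissues. Zero-FPKM entries are dropped from
log10 distribution summaries (no pseudocount), and genes need a total count
of >= 20 to enter distribution/clustering summaries.

## Integration

* **Overlap with direction concordance.** Genes significant in two
  comparisons are partitioned exactly into concordant (same fold-change
  sign) and discordant sets.
* **DEG/DSG overlap.** Side-by-side statistics; genes with opposing
  expression and splicing directions are annotated, not excluded.
* **AMD loci annotation.** Result rows restricted to a bundled list of ~100
  genes previously associated with AMD; emitted with +/- direction, signed
  fold change, padj, and the side of the contrast with higher expression.
* **Cross-dataset validation.** A discovery hit (significant as DEG, and as
  DSG when a splice set is supplied) is validated iff padj < 0.05 in an
  independent validation expression table; direction agreement is recorded
  but not required.
* **qPCR concordance.** 2^-ddCt relative quantification: per sample
  dCt = mean target Ct - mean reference Ct (triplicates), ddCt = case mean -
  control mean, fold = 2^-ddCt. Undetectable targets yield an undefined fold
  with a note; reciprocity fold(case, control) x fold(control, case) = 1
  holds exactly.

## Synthetic data

The generator's defaults mirror the study design: groups of 12 normal, 10
intermediate AMD and 5 neovascular donors for one tissue; 2000 genes with
4-12 exons; log-normal baseline means (median 100 counts, sigma = 1 on the
log scale); NB dispersion alpha = 0.05; per-sample library scale factors
uniform on [0.7, 1.4].

* **Exon counts** are NB draws (gamma-Poisson, var = mu + alpha mu^2) around
  sf_j * mu_g * pi_ge * 2^(beta_g x_j). Exon proportions are Dirichlet(5).
  Designated DE genes apply their log2 fold change beta in all non-reference
  groups. Designated differentially spliced genes use designed proportions
  (donor exon 0 at 0.45, acceptor exon 1 at 0.05, remainder equal) and move
  delta mass from exon 0 to exon 1 in the non-reference groups only; the
  gene-level mean is unchanged, so splicing truth is orthogonal to
  expression truth by construction. Valid shifts are delta < 0.4.
* **Allelic counts**: heterozygotes (per-site heterozygosity probability)
  draw an NB depth and binomial alt reads at the site's true fraction rho;
  homozygotes emit one allele only. Proxy genotypes match the target's
  heterozygosity with probability r^2 — a deliberate simplification of
  linkage disequilibrium, adequate because only the r^2 >= 0.8 threshold
  matters downstream.
* **Marker libraries** allocate a fixed library size multinomially so each
  panel's expected share equals its target fraction (defaults emulate clean
  RPE/choroid dissections: ~0.06% retina markers, ~0.65% RPE markers).

All randomness flows from one integer seed through numpy Generators, so
outputs are bit-reproducible across runs. The generator does **not** emulate
read-level artefacts (mapping bias, sequencing error, positional coverage),
covariates (age, sex), gene-gene correlation, or realistic LD structure —
so passing tests demonstrate the correctness and calibration of the
statistical procedures under their assumed sampling models, not robustness
to those real-data complications.

## Problem sizes and numerical choices

Null calibration and recovery checks run at 2000 genes with 10 samples per
group, ~500 tested heterozygotes for the ASE null and ~200 for power, and 50
planted splice genes at roughly 500 merged reads per exon — sizes chosen so
Monte-Carlo standard errors are small relative to the tolerances while the
full suite runs in well under a minute. Ties for the top splice exon break
to the lowest index within a 1e-12 relative band (the two log ratios of a
2-exon gene differ only in the last bit). Exact-test p-values use closed
binomial tail sums rather than naive pmf summation, agreeing with full
enumeration to < 1e-12 for all n <= 60.

## Known limitations

* No mapping-bias (WASP-style) correction for ASE; reference-allele bias in
  real alignments would violate the symmetric binomial null.
* The pooled splicing chi-square ignores replicate-level overdispersion
  (above).
* The Wald DE test is mildly anticonservative at small n and does not
  shrink fold changes; very-low-count genes have noisy dispersion estimates.
* Proxy confirmation models LD as a Bernoulli concordance, not haplotypes.
* r^2 values are inputs; the package does not compute LD from a reference
  panel, and covariate-adjusted validation models are consumed only as
  finished result tables.
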