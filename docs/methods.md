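# Methods

This note records the statistical models behind `poolex`, the design of
the synthetic-data generator, the numerical choices that matter, and the
limits of what the tests demonstrate.

## Study design assumed

Two independent trials of the same pooled-extremes design: per trial,
individuals from the low and high extremes of a quantitative trait are
pooled into three replicate RNA bulks per treatment and sequenced as six
libraries. All statistics operate on count-level summaries — a genes ×
libraries read-count matrix and a per-SNP, per-bulk table of
reference/alternate allele depths — not on reads or alignments. Read
trimming, mapping, transcript assembly and pile-up generation are
upstream of this package by design; so is the base-quality component of
the SNP-calling filters, which acts before allele tables exist.

## Differential gene expression

Counts for gene *g* in library *l* are modelled as negative binomial
with mean μ_gl and a **common dispersion** φ (var = μ + φμ²), the
classic two-group exact framework for small replicate numbers.

* **CPM filter.** cpm = count / library_size × 10⁶; genes need ≥ 1 CPM
  in ≥ 3 of the trial's 6 libraries (both thresholds inclusive and
  configurable). At a 70M-read library 1 CPM ≈ 70 reads, so the filter
  is effectively a minimum-evidence rule.
* **TMM factors.** Reference library = the one whose 75th-percentile
  count fraction is closest to the mean. Per library, M = log₂ ratio
  and A = mean log₂ abundance over genes nonzero in both libraries;
  the extreme 30% of M and 5% of A are rank-trimmed; the factor is the
  inverse-asymptotic-variance weighted mean of the kept M values
  (variances floored at 1e-12 so a gene carrying an entire library
  cannot dominate); factors are rescaled to geometric mean 1.
* **Dispersion.** Counts are scaled to the geometric mean of the
  effective (TMM-adjusted) library sizes; φ maximises the NB
  conditional log-likelihood given each group's sum, searched on
  log₁₀ φ ∈ [−6, 1] (bounded Brent, xatol 1e-4). A method-of-moments
  fallback (`dispersion_mom`: per-gene MoM, median across genes) is
  provided for diagnostics. On simulated null data with φ = 0.1 the
  CML estimate lands within a few percent.
* **Exact test.** Conditional on the total of the two group sums, the
  group-1 sum follows a negative hypergeometric law with parameters
  n₁/φ and n₂/φ; the two-sided p-value is the sum of all conditional
  probabilities not exceeding the observed one (tie tolerance 1e-10 in
  log space). For φ < 1e-8 the analytic Binomial(z, n₁/(n₁+n₂)) limit
  is used directly, because evaluating Γ-function differences at
  r ≈ 10¹⁰ loses more precision than the limit itself. Group sums are
  rounded to integers after scaling; at the default depths this
  rounding is ≪ 1 count in relative terms.
* **Fold change.** log₂((m_low + 0.125)/(m_high + 0.125)) on
  common-scale group means; the 0.125 prior keeps zero groups finite.
  Convention: negative = down-regulated in the low-trait samples.
* **FDR.** In-package Benjamini–Hochberg step-up (shared with the
  enrichment module), applied within the filtered gene set of each
  trial. Genes failing the filter in either trial are excluded from the
  cross-trial comparison; the cross-trial set requires FDR < α in both
  trials, then splits by fold-change sign.

## Differential allelic expression

Replicate depths are summed within treatment — pooling counts, not
averaging frequencies, which matters when replicate depths are
unbalanced. Filters follow the count-level part of common pooled
SNP-calling practice (per pooled treatment: depth ≥ 50, minor-allele
support ≥ 20, minor-allele frequency ≥ 0.01; a SNP passes if at least
one pooled treatment qualifies). The test is Pearson's chi-square on
the pooled 2×2 table, 1 df, no continuity correction — at the depths
this design produces (hundreds to thousands of reads per pooled
treatment) a Yates correction is immaterial — with a two-sided Fisher
exact fallback whenever an expected cell is below 5 (logged; the
reported statistic remains Pearson's).

Significance uses a deliberately conservative fixed per-SNP cutoff of
p ≤ 10⁻⁴ rather than a data-dependent family adjustment; the cutoff is
configurable (`--dae-p`) for users who prefer α/m. SNP identity across
trials is matched on (chrom, pos, ref, alt); records whose alleles are
recorded swapped in one trial are re-oriented before comparison. The
robust set requires significance in both trials **and** the same sign
of Δf = f_low − f_high (allele-B frequency difference); Δf = 0 never
counts as a direction. Robust DAE SNPs inside a cross-trial consistent
DE gene are labelled `cis_candidate`; other robust DAE SNPs
(`dae_only`) are putatively trans — intergenic SNPs, which have no host
gene, can never be cis candidates.

## Ka/Ks selection scan

Variant depths are pooled across all six bulks of a trial and filtered
(minor-allele count ≥ 4, total coverage between 20 and 2000). Passing
variants are classified against the gene models: strand-aware (alleles
reverse-complemented for '−' genes), frame-aware, with the stored
region label always recomputed from coordinates (the recomputation is
authoritative; disagreements are logged).

Site lengths use Nei–Gojobori (1986) equal-rate counting: each codon
position contributes the fraction of its three point mutations that are
synonymous to Ls, the rest to Ln, so Ln + Ls equals the CDS length
exactly — a property the tests verify against an exhaustive
mutate-and-translate enumeration. Stop-creating or stop-destroying
mutations count as nonsynonymous; stop→stop counts as synonymous. The
per-gene score is Ka/Ks = ((NS+1)/Ln) / ((SS+1)/Ls); the +1 pseudocount
keeps zero-SNP genes defined (their baseline is Ls/Ln ≈ 0.3–0.4, i.e.
apparent purifying selection), and the flag threshold is a **strict**
ratio > 1.5, per trial, intersected across trials.

Because the substitutions are within-population polymorphisms from
pooled RNA reads, not fixed interspecific differences, the statistic is
a pN/pS-style polymorphism ratio and inherits its caveats (segregating
deleterious variants inflate it); the Ka/Ks name is retained as the
conventional label for this screen. No multiple-hit correction
(Jukes–Cantor etc.) is applied — within-population divergence is far
too small for it to matter.

## Category enrichment

One-sided over-representation only: for each category, the upper
hypergeometric tail of the in-query/in-category 2×2 table, BH-adjusted
across the categories tested. The universe is the gene set eligible for
the upstream analysis (expression-filtered genes for the DE suites, all
annotated genes for DAE and selection suites). Categories come from a
user-supplied gene→category TSV; no ontology-graph propagation is
performed, so parent/child double counting is the caller's
responsibility.

## Synthetic-data generator

`syndata` emulates the study at desk scale. Defaults (a `SimConfig`):
2000 genes on 10 chromosomes; CDS of 60–300 codons with ≥ 1 intron,
UTRs, both strands, non-overlapping genes; 2 trials × 2 treatments × 3
bulks; expected library size 10⁶ (so a median gene draws ~500 reads per
library); NB dispersion 0.1; 10% DE genes at |log₂FC| = 2 applied to
the low treatment with the same sign in both trials; 25% of genes carry
one test SNP (region mix dominated by synonymous sites, plus ~4%
intergenic SNPs); per-bulk SNP depth Poisson around 250 with a
per-SNP log-normal factor (σ = 0.25), giving ~750 pooled reads per
treatment and ~1500 per trial — inside the Ka/Ks coverage window; 25%
of SNPs get a planted allele-frequency shift of 0.25 (half placed in DE
genes as cis, half elsewhere as trans); 5% of genes receive 10
nonsynonymous / 0 synonymous planted variants, which guarantees a true
Ka/Ks above the 1.5 threshold at every realised Ln/Ls.

Planted coding variants are chosen by searching codons for a mutation
of the desired effect and are re-verified by full-CDS translation;
the truth table records every planted label, and generation fails
loudly if any cis SNP is outside a DE gene or any region label
disagrees with coordinate reclassification. All randomness flows from
one seed through per-purpose substreams, so identical config + seed
gives byte-identical files.

What the generator does **not** emulate: sequencing error and false SNP
calls, mapping bias toward the reference allele, overdispersion of
allele counts beyond binomial (e.g. PCR duplicates), isoform structure,
correlated expression between genes, and library-composition artifacts
beyond a ±20% size jitter. Passing recovery tests therefore shows the
statistics are implemented correctly and calibrated under the assumed
count models — not that real pooled data meet those models.

## Numerical and edge-case policy

* Degenerate genes (all-zero counts) get p = 1, log₂FC = 0; degenerate
  2×2 tables (a zero marginal) get p = 1 with statistic 0.
* The DAE threshold is inclusive (p ≤ 10⁻⁴ is significant).
* BH adjustment enforces monotonicity by a reverse running minimum and
  clips at 1; NaN inputs are an error, never silently dropped.
* GTF parsing is strict: 9 tab-separated columns (errors name the line
  number), CDS length must be divisible by 3 (errors name the gene),
  unknown feature types are ignored with one warning per type.
* A variant whose reference allele contradicts the CDS base at its
  position is an error naming the position, not a silent skip.
* Coordinates are 1-based inclusive everywhere, including VCF export.

## Problem sizes used in tests

The default simulated study (2000 genes, ~1500 SNPs, 12 libraries) runs
the full pipeline in a few seconds; calibration suites pool ≥ 2000 null
units over three seeds. These sizes give binomial standard errors of
~0.005 on a 5% type-I rate and a few percent on recovery rates, tight
enough for the acceptance bands ([0.035, 0.065] on type-I; ≥ 90%
recovery; ≤ 2% false cis rate) without being wasteful.

## Known limitations

* The exact-test implementation targets calibration, not bit-equality
  with any particular DE tool; tagwise/trended dispersion shrinkage and
  GLM designs are out of scope.
* Transcript→gene collapsing (when one gene yields several assembled
  transcripts) is delegated to an upstream user-supplied id map; the
  pipeline keys everything by a single id string.
* Beta-binomial overdispersion of allelic counts is not modelled in the
  DAE test; with strongly duplicated libraries the chi-square will be
  anticonservative on real data.
* Enrichment FDR is BH across tested categories, which ignores the
  dependency induced by overlapping categories.
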