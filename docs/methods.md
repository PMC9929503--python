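# Methods

## The mapping problem

A colour phenotype segregates as an autosomal recessive in a two-line
breeding design: a wild-type line (WT, black; causal genotype `AA`) and a
mutant line (YM, yellow; `aa`). The pipeline localises and identifies the
causal variant from three kinds of evidence:

1. **Segregation ratios** across ten F1/F2 mating pairs confirm the
   inheritance mode;
2. a **case-control GWAS** over a 40-fish F2 panel (20 yellow, 20 black)
   finds the candidate interval;
3. a **bulk-segregant screen** over three pooled sequencing libraries
   narrows the interval's SNPs to those perfectly associated with the
   phenotype, and a **consequence caller** identifies the coding change.

All stages operate on standard formats (VCF with GT:DP, pooled allele
depths as TSV, FASTA, GFF3), so they run unchanged on real call sets; the
simulator exists to generate data with the exact statistical structure
the analysis assumes.

## Simulation model

**Genome.** Three 20 Mb chromosomes of i.i.d. random sequence; background
SNPs are placed by a Poisson draw at an expected density of 1e-5 per bp
(~600 genome-wide). A fraction `fixed_fraction = 0.5` of SNPs are fixed
differences between the two founder lines (the reference carries the WT
allele everywhere); the rest segregate *within* both lines at frequency
0.5, giving the screens true negatives to reject.

**Causal gene.** One gene is planted mid-chromosome-2:
5'UTR (50 bp) — CDS exon 1 (600 bp) — intron (300 bp) — CDS exon 2
(600 bp) — 3'UTR (100 bp), plus strand by default (minus strand
supported and tested). The CDS is random stop-free codons with ATG first,
TAA last, and TGG forced at the codon covering CDS position 383, so the
planted G→A variant at c.383 creates a TAG stop at codon 128.

**Meiosis.** Haldane model: crossover count per chromosome ~
Poisson(map length in Morgans) at a uniform 1 cM/Mb, breakpoints uniform,
no interference; the recombinant fraction at distance d Morgans is
(1 − e^(−2d))/2. 20 Mb chromosomes at 1 cM/Mb give 0.2 Morgans each —
enough map length that the perfectly associated window around the causal
site is sub-chromosomal.

**Panel and pools.** The mapping family is WT×YM founders → two F1
carriers → F2 offspring sampled until 20 yellow and 20 black accumulate.
Per-sample site depth is Poisson(12.91); a genotype is missing when fewer
than 2 reads cover it. Pools hold 24 fish each: WW and YY pools are
founder-line individuals, the F1 pool is fresh WT×YM offspring. Pool
depth per site is Poisson(mean coverage: 35.31 / 33.79 / 29.94 for
WW / YY / F1); each read draws one of the 48 haplotypes uniformly and is
miscalled with probability 0.01 to a uniformly random other base (so 1/3
of errors land on the other modelled allele and 2/3 on a third allele,
which is what the biallelic criterion screens).

**Scale.** The defaults are a desk-scale rendering of a whole-genome
study: ~600 SNPs instead of hundreds of thousands, three chromosomes
instead of a karyotype. Densities were chosen once from the closed form
for the expected perfect-association count,
2 × (fixed-SNP density per cM) / 0.4 ≈ 25, so the funnel endpoint has the
same order as a real single-locus study; the GWAS threshold, funnel
monotonicity and recovery behaviour do not depend on absolute SNP counts.

**Determinism.** One seed drives a fixed draw order (reference → founders
→ F1s → F2 panel → segregation cohorts → panel depths → pools); identical
(config, seed) reproduce byte-identical fixture files.

## Statistical procedures and numerical choices

**Segregation.** Pearson 1-df χ² without continuity correction (cohorts
are ~1500 fish; Yates would over-correct). Degenerate expectations
(all-black, all-yellow) are checked by exact concordance: one off-class
fish falsifies the cross. Ratios are reported to two decimals.

**Association.** Logistic regression (intercept + additive dosage) by
Newton/IRLS, vectorised across sites; convergence at step < 1e-10, max 40
iterations, steps damped to ≤10 per iteration to survive near-separated
likelihoods. A fit is declared separated when it fails to converge, the
Hessian degenerates, or |β| > 15 (odds ratios beyond e¹⁵ are not
estimable from 40 fish); such sites use a two-sided Fisher's exact test
on the allelic 2×2 table (minimum-likelihood rule), recorded in the
`method` column. Constant-dosage sites report p = 1. Missing genotypes are
dropped sample-wise at the affected site. The Wald test at n = 40 runs
slightly conservative (empirical size ~0.042 at nominal 0.05), which is
the safe direction for a Bonferroni screen. The threshold is
−log₁₀(α/N) at full precision; N is the post-QC site count.

**Site QC.** Biallelic, mean depth in [5, 250], call rate ≥ 0.95, all
thresholds inclusive.

**Peak region.** Chromosome of the global minimum p (ties broken
lexicographically); interval = [min, max] position of its significant
SNPs; the span in Mb is (end − start)/1e6, matching the convention in
which the printed boundaries of a 13.98 Mb interval differ by exactly
13,982,739 bp.

**Bulk-segregant screen.** Criteria are evaluated on allele-depth
fractions, not called genotypes, so "homozygous" needs a tolerance:
ε = 0.10 off-allele fraction at a minimum per-pool depth of 10. ε was set
from the error model — at ~30× pool depth and 1% sequencing error, two
miscalled reads are routine and a 5% tolerance would discard ~1% of true
fixed differences, while a site truly segregating within a line sits near
0.5 and is rejected regardless (p ~ 1e-6 at 30×). The F1 balance test
keeps sites with χ² goodness-of-fit p ≥ 0.001; the screen's purpose is to
discard gross imbalance (duplications, mismapping), and a looser α = 0.05
keep-rule would discard exactly 5% of genuinely balanced sites — including
the causal one in 1 run out of 20 — for no specificity gain. Stage order
(allele criteria + balance → interval → GWAS overlap → perfect
association) is fixed and recorded in the funnel report; the stage-1
criteria commute, so the order within stage 1 is presentational.

**Perfect association** is evaluated over non-missing genotypes (the
call-rate filter upstream guarantees ≥ 38/40 calls per site).

**Annotation.** Standard genetic code (configurable table id). Precedence
for region classes: CDS > UTR > intronic > intergenic; gene models are
assumed non-overlapping. HGVS strings are simplified (`c.383G>A`,
`p.W128*`, `p.A2=` for synonymous, `p.M1?` for start loss) without
transcript accessions; parsers regenerate the fields for round-trip
checks. Minus-strand variants are complemented before codon lookup;
strand symmetry is property-tested.

## What the simulation does and does not show

The generator reproduces the *statistical* structure the pipeline relies
on: Mendelian transmission, Haldane linkage decay, fixed line differences
vs within-line polymorphism, depth-limited genotype missingness, and
binomial pooled allele sampling with a third-allele error channel. It
does **not** model mapping artifacts, indels or multi-allelic sites,
reference bias, duplicated regions (the main real-world source of allele
imbalance the balance test exists for), linked selection, or family
structure beyond the single mapping pedigree. Passing tests therefore
demonstrate correctness of the statistical machinery under the idealised
model, not robustness to alignment- or caller-level pathologies.

## Problem sizes used in the checks

Simulation-based checks run at the sizes stated in their tests: 100,000
gametes for map-function and Mendelian-fraction checks, 10,000 replicates
for test-size calibration, 1000 replicate sites for screen operating
characteristics, 1000 random substitutions for the translation oracle,
and 50 seeded end-to-end runs for causal recovery. These sizes make
binomial Monte Carlo error small relative to every asserted tolerance.

## Known limitations

* The logistic fallback changes the test statistic family mid-scan;
  ranking across the logistic/Fisher boundary is coherent in practice
  (both are monotone in association strength) but p-values are not drawn
  from a single null family.
* The candidate-interval rule (min–max of significant SNPs on the top
  chromosome) is deliberately simple; no LD pruning or distance gap rule
  is applied.
* Pool composition assumes equal DNA contribution per fish; unequal
  pooling would over-disperse allele fractions relative to the binomial
  model.
* The fallback Fisher test is two-sided by table probability; other
  two-sided conventions (doubling the one-sided p) would give slightly
  different values at extreme tables.
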