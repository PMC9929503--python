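# recessmap

Mapping a recessive Mendelian trait locus in an F2 fish cross, end to end:
Mendelian segregation tests, per-SNP case-control GWAS with a Bonferroni
genome-wide threshold, a three-pool bulk-segregant SNP filtering cascade,
and codon-level variant-effect annotation — together with a seeded forward
simulator of the whole breeding design that generates the study's data
structure (VCF/FASTA/GFF3/TSV) from scratch.

The motivating setting is a colour morph segregating as an autosomal
recessive: crosses between a wild-type (black, `A`) and a mutant (yellow,
`a`) line give all-black F1 carriers, 3:1 black:yellow F2 intercross
ratios and 1:1 backcross ratios. Sequencing 20 affected + 20 unaffected F2
fish and three 24-fish DNA bulks (wild-type line, mutant line, F1
carriers) localises the locus; the causal change in the simulated study is
a G→A transition at coding position 383 of the planted gene, turning the
TGG codon for tryptophan 128 into a TAG stop (c.383G>A, p.W128*) — the
classic loss-of-function signature of pigmentation genes such as
*slc45a2*.

## The statistics at the core

* **Segregation**: for each cross, the expected black:yellow class follows
  from the parental genotypes (all-black, 3:1, 1:1, all-yellow); observed
  counts are tested with a 1-df Pearson χ² goodness-of-fit,
  χ² = Σ (O−E)²/E.
* **Association**: per SNP, logistic regression of phenotype on additive
  alt-allele dosage (Wald test). Perfectly associated sites have no finite
  MLE, so on separation the test falls back to a two-sided Fisher's exact
  test on the 2×2 allelic table. Genome-wide significance is
  −log₁₀(p) ≥ −log₁₀(α/N) with α = 0.01 and N the number of SNPs tested;
  the candidate interval is the min–max span of significant SNPs on the
  chromosome carrying the strongest signal.
* **Bulk-segregant screen**: a SNP survives if (i) it is biallelic,
  (ii) the WW pool matches the reference allele and the YY pool the
  variant allele (off-allele read fraction ≤ ε) while the F1 pool shows
  both, and the F1 pool's allele ratio is compatible with 1:1 by
  χ² = (ref−alt)²/(ref+alt). Survivors are intersected with the GWAS
  interval and significant set, then reduced to SNPs perfectly associated
  in the F2 panel (every affected fish hom-alt, every unaffected fish
  carrying ≥ 1 reference allele).
* **Annotation**: genomic→spliced-CDS coordinate mapping (both strands),
  codon extraction, standard genetic code, simplified HGVS c./p. strings.
* **Simulation**: Haldane meiosis (Poisson crossovers at 1 cM/Mb, no
  interference, r = (1−e^(−2d))/2), founder lines fixed for opposite
  alleles at half the SNPs, binomial pooled read sampling with a 1%
  per-read error.

## Worked example

The numbered scripts under `analysis/` run the study step by step, writing
tables under `results/`:

```
python analysis/01_simulate.py --seed 1
python analysis/02_segregation.py
python analysis/03_gwas.py
python analysis/04_bsa.py
python analysis/05_annotate.py
```

With seed 1 this prints (abridged):

```
simulated 605 SNPs (301 fixed line differences), 40 panel fish, 3 pools

 1# YW♀×YW♂   1126  374  3.01  3:1  p=0.95
 5# YW♀×YY♂    740  760  0.97  1:1  p=0.61
 9# YY♂×WW♀   1500    0   inf  all-black  concordant
8/8 testable crosses consistent with their Mendelian ratio at alpha=0.05

605/605 sites passed QC; -log10(p) threshold 4.78
peak: chr2:49,357-15,776,918 (15.73 Mb, 116 significant SNPs)

allele criteria + 1:1 balance: 605 -> 301
within candidate interval: 301 -> 76
overlap GWAS-significant: 76 -> 76
perfect association: 76 -> 28

consequence summary: {"intergenic": 27, "stop_gain": 1}
putative causal variant: chr2:10000432 G>A (c.383G>A, p.W128*) in gene1
```

Reading the output: the eight testable crosses match their Mendelian
expectations; the association scan finds a single peak on the causal
chromosome; the bulk-segregant funnel narrows 605 SNPs to 28 perfectly
associated candidates; and exactly one of them is protein-coding — the
planted stop gain at codon 128.

The same stages are available as a console tool operating on real files
(`recessmap simulate | segregate | gwas | bsa | annotate | run`), e.g.

```
recessmap gwas --vcf panel.vcf --phenotypes phenotypes.tsv --alpha 0.01
```

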