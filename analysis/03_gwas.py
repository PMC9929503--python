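#!/usr/bin/env python
"""Case-control GWAS over the 40-fish F2 panel.

Reads the panel VCF and phenotype table from results/fixtures/, applies
the depth/missingness site filter, scans every SNP with the logistic
(Fisher-fallback) association test, computes the Bonferroni threshold
-log10(0.01/N), and extracts the candidate peak interval. Writes
results/gwas.tsv, results/manhattan.tsv and results/region.json.
"""

import argparse
import json

import numpy as np

from recessmap import assoc, io


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--fixtures", default="results/fixtures")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    variants, G, DP, samples = io.read_vcf(f"{args.fixtures}/panel.vcf")
    pheno = io.read_phenotypes(f"{args.fixtures}/phenotypes.tsv").set_index("sample")
    y = np.array([1 if pheno.loc[s, "phenotype"] == "yellow" else 0 for s in samples])

    keep = np.array(
        [
            assoc.site_filter(G[i], DP[i], biallelic=variants.loc[i, "n_alleles"] == 2)[0]
            for i in range(len(variants))
        ]
    )
    scan, threshold = assoc.genome_scan(
        variants.loc[keep, ["chrom", "pos", "ref", "alt"]], G[keep], y
    )
    region = assoc.peak_region(scan)

    io.write_tsv(scan, f"{args.outdir}/gwas.tsv")
    io.write_tsv(
        scan[["chrom", "pos", "neglog10p", "significant"]],
        f"{args.outdir}/manhattan.tsv",
    )
    region_d = None
    if region:
        region_d = {"chrom": region.chrom, "start": region.start, "end": region.end,
                    "span_mb": region.span_mb, "n_significant": region.n_significant}
    with open(f"{args.outdir}/region.json", "w") as fh:
        json.dump({"threshold": threshold, "region": region_d}, fh, indent=2)

    print(f"{int(keep.sum())}/{len(keep)} sites passed QC; "
          f"-log10(p) threshold {threshold:.2f}")
    if region:
        print(f"peak: {region.chrom}:{region.start:,}-{region.end:,} "
              f"({region.span_mb:.2f} Mb, {region.n_significant} significant SNPs)")
    else:
        print("no genome-wide significant SNPs")


if __name__ == "__main__":
    main()
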