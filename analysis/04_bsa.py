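#!/usr/bin/env python
"""Three-pool bulk-segregant screen and funnel report.

Reads pool allele depths, the GWAS scan and region, and the panel
genotypes; applies the cascade (allele criteria + 1:1 balance, region
intersection, GWAS-significant overlap, perfect association) and writes
results/funnel.tsv plus results/candidates_raw.tsv.
"""

import argparse
import json

import numpy as np

from recessmap import bsa, io
from recessmap.assoc import PeakRegion


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--fixtures", default="results/fixtures")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    pools = io.read_tsv(f"{args.fixtures}/pools.tsv")
    scan = io.read_tsv(f"{args.outdir}/gwas.tsv")
    with open(f"{args.outdir}/region.json") as fh:
        meta = json.load(fh)
    region = None
    if meta["region"]:
        r = meta["region"]
        region = PeakRegion(r["chrom"], r["start"], r["end"], r["n_significant"])

    variants, G, _, samples = io.read_vcf(f"{args.fixtures}/panel.vcf")
    pheno = io.read_phenotypes(f"{args.fixtures}/phenotypes.tsv").set_index("sample")
    ph = np.array([pheno.loc[s, "phenotype"] for s in samples])
    sig = set(zip(scan.loc[scan["significant"], "chrom"],
                  scan.loc[scan["significant"], "pos"]))

    funnel = bsa.apply_cascade(
        variants[["chrom", "pos", "ref", "alt"]], pools, region, sig, G, ph
    )
    io.write_tsv(funnel.to_frame(), f"{args.outdir}/funnel.tsv")
    io.write_tsv(funnel.candidates, f"{args.outdir}/candidates_raw.tsv")
    for name, n_in, n_out in funnel.stages:
        print(f"{name}: {n_in} -> {n_out}")
    print(f"final perfectly associated SNPs: {len(funnel.candidates)}")


if __name__ == "__main__":
    main()
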