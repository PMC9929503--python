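#!/usr/bin/env python
"""Codon-level consequences of the final candidate SNPs.

Reads the surviving candidates, the gene models (GFF3) and the reference
(FASTA); classifies each candidate (CDS/UTR/intronic/intergenic), calls
codon consequences for CDS hits and writes results/candidates.tsv with a
per-class summary. A stop gain, if present, is the putative causal call.
"""

import argparse
import json

from recessmap import io
from recessmap.annotate import annotate_candidates


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--fixtures", default="results/fixtures")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    genes = io.read_gff3(f"{args.fixtures}/genes.gff3")
    ref_seqs = io.read_fasta(f"{args.fixtures}/reference.fa")
    candidates = io.read_tsv(f"{args.outdir}/candidates_raw.tsv")

    table, summary = annotate_candidates(candidates, genes, ref_seqs)
    io.write_tsv(table, f"{args.outdir}/candidates.tsv")
    print("consequence summary:", json.dumps(summary, sort_keys=True))
    stops = table[table["consequence"] == "stop_gain"]
    if len(stops):
        t = stops.iloc[0]
        print(f"putative causal variant: {t['chrom']}:{t['pos']} {t['ref']}>{t['alt']} "
              f"({t['hgvs_c']}, {t['hgvs_p']}) in {t['gene']}")
    else:
        print("no stop-gain candidate")


if __name__ == "__main__":
    main()
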