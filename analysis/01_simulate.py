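#!/usr/bin/env python
"""Simulate the mapping study and write the text fixture set.

Builds the default study: three 20 Mb chromosomes, a planted gene with a
G>A stop gain at CDS position 383, WT/YM founder lines, ten F1/F2 crosses,
a 20 yellow + 20 black F2 sequencing panel and three 24-fish DNA bulks.
Outputs land in results/fixtures/ (FASTA, GFF3, VCF, pool TSV, phenotype
TSV, manifest) and feed the later numbered steps.
"""

import argparse
import json

from recessmap.pipeline import RunConfig, simulate_study, write_fixture_set


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/fixtures")
    args = ap.parse_args()

    config = RunConfig(seed=args.seed)
    study = simulate_study(config)
    files = write_fixture_set(study, args.outdir)
    print(f"simulated {len(study.reference.variants)} SNPs "
          f"({int(study.reference.variants.df['is_fixed'].sum())} fixed line differences), "
          f"{len(study.panel)} panel fish, 3 pools")
    print(json.dumps(files, indent=2))


if __name__ == "__main__":
    main()
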