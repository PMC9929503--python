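#!/usr/bin/env python
"""Test the simulated cross cohorts against Mendelian expectations.

Reads the cohort counts written by 01_simulate.py, runs the chi-square
goodness-of-fit per cross (3:1 intercrosses, 1:1 backcrosses, exact
concordance for the all-black/all-yellow crosses) and writes
results/segregation.tsv.
"""

import argparse

from recessmap import io
from recessmap.models import DEFAULT_CROSS_PLANS
from recessmap.segregation import segregation_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--counts", default="results/fixtures/segregation_counts.tsv")
    ap.add_argument("--out", default="results/segregation.tsv")
    args = ap.parse_args()

    counts = io.read_tsv(args.counts)
    plan = {p.label: (p.dam_genotype, p.sire_genotype) for p in DEFAULT_CROSS_PLANS}
    table = segregation_table(counts, plan)
    io.write_tsv(table, args.out)
    print(table.to_string(index=False))
    testable = table[table["expected"].isin(["3:1", "1:1"])]
    print(f"\n{(testable['p'] >= 0.05).sum()}/{len(testable)} testable crosses "
          "consistent with their Mendelian ratio at alpha=0.05")


if __name__ == "__main__":
    main()
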