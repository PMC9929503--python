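"""Readers/writers for the pipeline's on-disk formats.

FASTA via Biopython, VCF v4.2 via pysam (GT:DP per F2 sample), GFF3 via
gffutils on the read side, pool allele depths and phenotypes as TSV.
All writers are deterministic: identical inputs give identical bytes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, VariantTable

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Minimal gene/mRNA/exon/CDS feature rows with ID=/Parent= links."""
    lines = ["##gff-version 3"]
    for g in genes:
        rna_id = f"{g.gene_id}.t1"
        lines.append(
            f"{g.chrom}\trecessmap\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
        lines.append(
            f"{g.chrom}\trecessmap\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={rna_id};Parent={g.gene_id}"
        )
        for i, (s, e) in enumerate(g.exons, 1):
            lines.append(
                f"{g.chrom}\trecessmap\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={rna_id}.exon{i};Parent={rna_id}"
            )
        # phase per CDS segment, in translation order
        ordered = g.cds if g.strand == "+" else list(reversed(g.cds))
        phases = {}
        acc = 0
        for (s, e) in ordered:
            phases[(s, e)] = (3 - acc % 3) % 3
            acc += e - s + 1
        for i, (s, e) in enumerate(g.cds, 1):
            lines.append(
                f"{g.chrom}\trecessmap\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phases[(s, e)]}\t"
                f"ID={rna_id}.cds{i};Parent={rna_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons, cds = [], []
        for feat in db.children(g, featuretype="exon"):
            exons.append((feat.start, feat.end))
        for feat in db.children(g, featuretype="CDS"):
            cds.append((feat.start, feat.end))
        genes.append(
            GeneModel(gene_id=g.id, chrom=g.seqid, strand=g.strand,
                      exons=sorted(exons), cds=sorted(cds))
        )
    return genes


# ---------------------------------------------------------------------------
# VCF (individual genotypes, GT:DP)
# ---------------------------------------------------------------------------


def write_vcf(
    variants: pd.DataFrame,
    genotypes: np.ndarray,
    depths: np.ndarray,
    samples: list[str],
    chrom_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """VCF v4.2 with GT and DP; genotypes are dosages with -1 = missing."""
    header = pysam.VariantHeader()
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for s in samples:
        header.add_sample(s)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, row in enumerate(variants.itertuples(index=False)):
            rec = vcf.new_record(
                contig=row.chrom, start=row.pos - 1, stop=row.pos,
                alleles=(row.ref, row.alt),
            )
            for j, s in enumerate(samples):
                g = int(genotypes[i, j])
                rec.samples[s]["GT"] = gt_map.get(g, (None, None))
                rec.samples[s]["DP"] = int(depths[i, j])
            vcf.write(rec)


def read_vcf(path: str | Path) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, list[str]]:
    """Returns (variants frame, dosage matrix, depth matrix, sample names).

    Multi-allelic records are kept in the frame with n_alleles recorded so
    the site filter can drop them; dosage counts the first alt allele.
    """
    rows, gts, dps = [], [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        chrom_lengths = {
            name: (c.length or 0) for name, c in vcf.header.contigs.items()
        }
        for rec in vcf:
            alts = rec.alts or ()
            rows.append(
                {
                    "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                    "alt": alts[0] if alts else ".",
                    "n_alleles": 1 + len(alts),
                }
            )
            g_row, d_row = [], []
            for s in samples:
                call = rec.samples[s]
                alleles = call.get("GT", (None, None))
                if alleles is None or any(a is None for a in alleles):
                    g_row.append(-1)
                else:
                    g_row.append(sum(1 for a in alleles if a == 1))
                d_row.append(call.get("DP") or 0)
            gts.append(g_row)
            dps.append(d_row)
    variants = pd.DataFrame(rows)
    variants.attrs["chrom_lengths"] = chrom_lengths
    return variants, np.asarray(gts, dtype=np.int8), np.asarray(dps, dtype=np.int32), samples


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_phenotypes(samples: list[str], phenotypes: list[str], path: str | Path) -> None:
    pd.DataFrame({"sample": samples, "phenotype": phenotypes}).to_csv(
        path, sep="\t", index=False
    )


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "phenotype"}.issubset(df.columns):
        raise ValueError("phenotype table needs 'sample' and 'phenotype' columns")
    bad = set(df["phenotype"]) - {"black", "yellow"}
    if bad:
        raise ValueError(f"unknown phenotype labels: {bad}")
    return df


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
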