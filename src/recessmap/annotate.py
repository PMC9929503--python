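"""Codon-level consequence calls for candidate variants.

Classifies each variant against the gene models (CDS / intronic / UTR /
intergenic), maps CDS hits to 1-based spliced-CDS coordinates (c.
positions; minus-strand genes count from the 3' genomic end with
complemented alleles), and calls the codon-level consequence under the
standard genetic code with simplified HGVS-style c. and p. strings.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .models import GeneModel, revcomp

_AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V",
}

REGION_CLASSES = ("CDS", "UTR", "intronic", "intergenic")
CONSEQUENCES = ("stop_gain", "missense", "synonymous", "stop_loss", "start_loss")


@dataclass(frozen=True)
class VariantEffect:
    chrom: str
    pos: int
    ref: str
    alt: str
    region_class: str
    gene_id: str | None = None
    cds_pos: int | None = None
    codon_index: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    consequence: str | None = None
    hgvs_c: str | None = None
    hgvs_p: str | None = None

    def to_row(self) -> dict:
        return {
            "chrom": self.chrom, "pos": self.pos, "ref": self.ref, "alt": self.alt,
            "class": self.region_class, "gene": self.gene_id, "cds_pos": self.cds_pos,
            "codon": self.codon_index, "ref_codon": self.ref_codon,
            "alt_codon": self.alt_codon, "consequence": self.consequence,
            "hgvs_c": self.hgvs_c, "hgvs_p": self.hgvs_p,
        }


def translate_codon(codon: str, table_id: int = 1) -> str:
    """One-letter amino acid for a codon; '*' for stop."""
    table = unambiguous_dna_by_id[table_id]
    codon = codon.upper()
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def classify_region(chrom: str, pos: int, genes: list[GeneModel]) -> tuple[str, GeneModel | None]:
    """Region class by containment, strand-independent.

    CDS beats UTR beats intronic; positions outside every gene span are
    intergenic. Gene models are assumed non-overlapping.
    """
    for gene in genes:
        if gene.chrom != chrom or not gene.contains(pos):
            continue
        if gene.in_cds(pos):
            return "CDS", gene
        if gene.in_exon(pos):
            return "UTR", gene
        return "intronic", gene
    return "intergenic", None


def genomic_to_cds(pos: int, gene: GeneModel) -> int:
    """1-based spliced-CDS coordinate of a genomic position (error if not CDS)."""
    return gene.genomic_to_cds(pos)


def codon_consequence(
    cds_pos: int,
    ref: str,
    alt: str,
    cds_seq: str,
    table_id: int = 1,
) -> dict:
    """Consequence of a single-base substitution at a spliced-CDS position.

    ``ref``/``alt`` are coding-strand bases; ``cds_seq`` is the reference
    spliced CDS. Raises if the reference allele disagrees with the CDS.
    """
    if not 1 <= cds_pos <= len(cds_seq):
        raise ValueError(f"CDS position {cds_pos} outside 1..{len(cds_seq)}")
    ref, alt = ref.upper(), alt.upper()
    if cds_seq[cds_pos - 1].upper() != ref:
        raise ValueError(
            f"reference allele {ref!r} does not match CDS base "
            f"{cds_seq[cds_pos - 1]!r} at position {cds_pos}"
        )
    if ref == alt:
        raise ValueError("ref and alt alleles must differ")
    codon_index = math.ceil(cds_pos / 3)
    cstart = (codon_index - 1) * 3
    ref_codon = cds_seq[cstart : cstart + 3].upper()
    within = cds_pos - 1 - cstart
    alt_codon = ref_codon[:within] + alt + ref_codon[within + 1 :]
    ref_aa = translate_codon(ref_codon, table_id)
    alt_aa = translate_codon(alt_codon, table_id)

    if codon_index == 1 and ref_codon == "ATG" and alt_codon != "ATG":
        consequence = "start_loss"
        hgvs_p = "p.M1?"
    elif ref_aa != "*" and alt_aa == "*":
        consequence = "stop_gain"
        hgvs_p = f"p.{ref_aa}{codon_index}*"
    elif ref_aa == "*" and alt_aa != "*":
        consequence = "stop_loss"
        hgvs_p = f"p.*{codon_index}{alt_aa}"
    elif ref_aa == alt_aa:
        consequence = "synonymous"
        hgvs_p = f"p.{ref_aa}{codon_index}="
    else:
        consequence = "missense"
        hgvs_p = f"p.{ref_aa}{codon_index}{alt_aa}"

    return {
        "cds_pos": cds_pos,
        "codon_index": codon_index,
        "ref_codon": ref_codon,
        "alt_codon": alt_codon,
        "ref_aa": ref_aa,
        "alt_aa": alt_aa,
        "consequence": consequence,
        "hgvs_c": f"c.{cds_pos}{ref}>{alt}",
        "hgvs_p": hgvs_p,
    }


_HGVS_C = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_HGVS_P = re.compile(r"^p\.(\*|[A-Z])(\d+)(\*|=|\?|[A-Z])$")


def parse_hgvs_c(s: str) -> tuple[int, str, str]:
    m = _HGVS_C.match(s)
    if not m:
        raise ValueError(f"unparsable c. string: {s!r}")
    return int(m.group(1)), m.group(2), m.group(3)


def parse_hgvs_p(s: str) -> tuple[str, int, str]:
    m = _HGVS_P.match(s)
    if not m:
        raise ValueError(f"unparsable p. string: {s!r}")
    return m.group(1), int(m.group(2)), m.group(3)


def annotate_variant(
    chrom: str, pos: int, ref: str, alt: str,
    genes: list[GeneModel], ref_seqs: dict[str, str],
) -> VariantEffect:
    region, gene = classify_region(chrom, pos, genes)
    if region != "CDS":
        return VariantEffect(chrom, pos, ref, alt, region_class=region,
                             gene_id=gene.gene_id if gene else None)
    if chrom not in ref_seqs:
        raise KeyError(f"chromosome {chrom!r} absent from the reference")
    cds_seq = gene.cds_sequence(ref_seqs[chrom])
    cds_pos = gene.genomic_to_cds(pos)
    c_ref, c_alt = (ref, alt) if gene.strand == "+" else (revcomp(ref), revcomp(alt))
    eff = codon_consequence(cds_pos, c_ref, c_alt, cds_seq)
    return VariantEffect(
        chrom, pos, ref, alt, region_class="CDS", gene_id=gene.gene_id,
        cds_pos=eff["cds_pos"], codon_index=eff["codon_index"],
        ref_codon=eff["ref_codon"], alt_codon=eff["alt_codon"],
        consequence=eff["consequence"], hgvs_c=eff["hgvs_c"], hgvs_p=eff["hgvs_p"],
    )


def annotate_candidates(
    candidates: pd.DataFrame,
    genes: list[GeneModel],
    ref_seqs: dict[str, str],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every candidate; returns the effect table and per-class
    summary counts (CDS rows counted by their consequence)."""
    effects = [
        annotate_variant(r["chrom"], int(r["pos"]), r["ref"], r["alt"], genes, ref_seqs)
        for _, r in candidates.iterrows()
    ]
    table = pd.DataFrame([e.to_row() for e in effects]) if effects else pd.DataFrame(
        columns=["chrom", "pos", "ref", "alt", "class", "gene", "cds_pos", "codon",
                 "ref_codon", "alt_codon", "consequence", "hgvs_c", "hgvs_p"]
    )
    summary: dict[str, int] = {}
    for e in effects:
        key = e.consequence if e.region_class == "CDS" else e.region_class
        summary[key] = summary.get(key, 0) + 1
    return table, summary
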