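"""Core domain types shared across the mapping pipeline.

Coordinates are 1-based inclusive throughout (VCF/GFF3 convention).
Genotypes are alt-allele dosages: 0 (hom ref), 1 (het), 2 (hom alt),
-1 for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Variant:
    """One biallelic SNP site."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    is_causal: bool = False

    def __post_init__(self):
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-nucleotide substitutions are modelled")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")


class VariantTable:
    """Ordered list of biallelic SNPs, sorted by (chromosome, position).

    Wraps a DataFrame with columns chrom/pos/ref/alt/is_causal (and
    optionally is_fixed, marking fixed differences between founder lines)
    plus the chromosome lengths, which the recombination model needs.
    """

    def __init__(self, df: pd.DataFrame, chrom_lengths: dict[str, int]):
        required = {"chrom", "pos", "ref", "alt", "is_causal"}
        if not required.issubset(df.columns):
            raise ValueError(f"variant table needs columns {sorted(required)}")
        order = {c: i for i, c in enumerate(chrom_lengths)}
        unknown = set(df["chrom"]) - set(order)
        if unknown:
            raise ValueError(f"variants on chromosomes without length: {unknown}")
        key = df["chrom"].map(order)
        self.df = (
            df.assign(_k=key)
            .sort_values(["_k", "pos"], kind="mergesort")
            .drop(columns="_k")
            .reset_index(drop=True)
        )
        self.chrom_lengths = dict(chrom_lengths)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def positions(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Contiguous (chromosome, row-slice) pairs in table order."""
        out = []
        chroms = self.df["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out.append((chroms[start], slice(start, i)))
                start = i
        return out

    def causal_index(self) -> int:
        idx = np.flatnonzero(self.df["is_causal"].to_numpy())
        if len(idx) != 1:
            raise ValueError(f"expected exactly one causal variant, found {len(idx)}")
        return int(idx[0])

    def subset(self, mask_or_index) -> "VariantTable":
        sub = self.df.loc[mask_or_index].reset_index(drop=True)
        return VariantTable(sub, self.chrom_lengths)


@dataclass
class Individual:
    """A diploid individual: two haplotypes of 0/1 allele indices."""

    id: str
    haplotypes: np.ndarray  # shape (2, n_variants), uint8
    line: str = "F2"  # WT | YM | F1 | F2
    sex: str | None = None

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] != 2:
            raise ValueError("haplotypes must have shape (2, n_variants)")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("allele indices must be 0 or 1")

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def dosage(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0).astype(np.int8)


@dataclass(frozen=True)
class CrossPlan:
    """One mating pair with the parents' genotypes at the causal locus."""

    label: str
    dam_genotype: str  # AA | Aa | aa
    sire_genotype: str
    n_offspring: int = 500

    def __post_init__(self):
        for g in (self.dam_genotype, self.sire_genotype):
            if g not in ("AA", "Aa", "aa"):
                raise ValueError(f"invalid causal genotype {g!r}")
        if self.n_offspring <= 0:
            raise ValueError("n_offspring must be positive")


#: The ten F1 intercross / backcross mating pairs of the breeding design.
#: Line codes: WY = WT dam x YM sire F1 (carrier, Aa); YW = reciprocal F1 (Aa);
#: WW = wild-type line (AA); YY = yellow-mutant line (aa).
DEFAULT_CROSS_PLANS: tuple[CrossPlan, ...] = (
    CrossPlan("1# YW♀×YW♂", "Aa", "Aa"),
    CrossPlan("2# WY♀×WY♂", "Aa", "Aa"),
    CrossPlan("3# YW♀×WY♂", "Aa", "Aa"),
    CrossPlan("4# WY♀×YW♂", "Aa", "Aa"),
    CrossPlan("5# YW♀×YY♂", "Aa", "aa"),
    CrossPlan("6# YY♀×YW♂", "aa", "Aa"),
    CrossPlan("7# WY♀×YY♂", "Aa", "aa"),
    CrossPlan("8# YY♀×WY♂", "aa", "Aa"),
    CrossPlan("9# YY♂×WW♀", "AA", "aa"),
    CrossPlan("10# YY♀×WW♂", "aa", "AA"),
)


@dataclass(frozen=True)
class PoolSpec:
    """One DNA bulk: who goes in and how deeply it is sequenced."""

    pool_id: str  # WW | YY | F1het
    n_individuals: int = 24
    mean_coverage: float = 30.0
    error_rate: float = 0.01

    def __post_init__(self):
        if self.pool_id not in ("WW", "YY", "F1het"):
            raise ValueError(f"unknown pool id {self.pool_id!r}")
        if self.n_individuals <= 0:
            raise ValueError("pool must contain at least one individual")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be non-negative")


@dataclass
class GeneModel:
    """A gene's exon/CDS structure with genomic<->CDS coordinate mapping.

    ``exons`` and ``cds`` are genomic (start, end) pairs, 1-based inclusive,
    stored in ascending genomic order regardless of strand; translation
    order is derived from ``strand``.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        for name, segs in (("exons", self.exons), ("cds", self.cds)):
            segs = sorted(tuple(s) for s in segs)
            for (s, e) in segs:
                if s > e:
                    raise ValueError(f"{name} segment with start > end: {(s, e)}")
            for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping {name} segments")
            setattr(self, name, list(segs))
        if self.cds_length % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        for (s, e) in self.cds:
            if not any(xs <= s and e <= xe for (xs, xe) in self.exons):
                raise ValueError("every CDS segment must lie inside an exon")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for (s, e) in self.cds)

    @property
    def start(self) -> int:
        return min(s for (s, _) in self.exons)

    @property
    def end(self) -> int:
        return max(e for (_, e) in self.exons)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for (s, e) in self.exons)

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for (s, e) in self.cds)

    def _cds_translation_order(self) -> list[tuple[int, int]]:
        return self.cds if self.strand == "+" else list(reversed(self.cds))

    def genomic_to_cds(self, pos: int) -> int:
        """1-based offset along the spliced CDS, in translation order."""
        offset = 0
        for (s, e) in self._cds_translation_order():
            if s <= pos <= e:
                return offset + (pos - s + 1 if self.strand == "+" else e - pos + 1)
            offset += e - s + 1
        raise ValueError(f"position {pos} is not inside the CDS of {self.gene_id}")

    def cds_to_genomic(self, cds_pos: int) -> int:
        if not 1 <= cds_pos <= self.cds_length:
            raise ValueError(f"CDS position {cds_pos} out of range 1..{self.cds_length}")
        offset = cds_pos - 1
        for (s, e) in self._cds_translation_order():
            seg_len = e - s + 1
            if offset < seg_len:
                return s + offset if self.strand == "+" else e - offset
            offset -= seg_len
        raise AssertionError("unreachable")

    def cds_sequence(self, chrom_seq: str) -> str:
        """Spliced CDS on the coding strand, given the chromosome sequence."""
        parts = [chrom_seq[s - 1 : e] for (s, e) in self.cds]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)


def expected_ratio_label(dam_genotype: str, sire_genotype: str) -> str:
    """Expected black:yellow class for a cross, from the carrier genotypes.

    Yellow is recessive: only aa offspring are yellow.
    """
    for g in (dam_genotype, sire_genotype):
        if g not in ("AA", "Aa", "aa"):
            raise ValueError(f"invalid causal genotype {g!r}")
    gts = {dam_genotype, sire_genotype}
    if "AA" in gts:
        return "all-black"
    if gts == {"Aa"}:
        return "3:1"
    if gts == {"Aa", "aa"}:
        return "1:1"
    return "all-yellow"  # aa x aa
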