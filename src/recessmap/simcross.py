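"""Seeded forward simulator of the mapping cross.

Emulates the breeding design behind a recessive colour locus: two founder
lines fixed for opposite alleles at a planted causal stop-gain SNP, F1
carriers, F2 intercross offspring with Haldane recombination (Poisson
crossovers, no interference), a 20-case/20-control F2 sequencing panel,
and three pooled DNA bulks (WW, YY, F1 heterozygotes) with binomially
sampled read depths.

Draw order under one seed is fixed and documented: reference -> founders
-> F1s -> F2 panel -> segregation cohorts -> pools, so identical
(config, seed) pairs reproduce byte-identical fixture files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    DEFAULT_CROSS_PLANS,
    CrossPlan,
    GeneModel,
    Individual,
    PoolSpec,
    VariantTable,
    revcomp,
)

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GenomeSpec:
    """Layout of the simulated genome and the planted causal allele.

    The defaults give three 20 Mb chromosomes at ~1 SNP per 100 kb
    (~600 SNPs genome-wide, half of them fixed line differences) with the
    causal gene mid-chromosome-2. At 1 cM/Mb the causal chromosome
    carries ~20 cM of map, so across the 80 meioses of a 40-fish F2
    panel the perfectly associated window holds an expected
    2 x 5 SNPs/cM / 0.4 = 25 fixed SNPs, a funnel endpoint of the same
    order as a real single-locus mapping study.
    """

    chromosomes: tuple[tuple[str, int], ...] = (
        ("chr1", 20_000_000),
        ("chr2", 20_000_000),
        ("chr3", 20_000_000),
    )
    snp_density: float = 1e-5  # expected background SNPs per bp
    fixed_fraction: float = 0.5  # fraction of SNPs fixed between founder lines
    causal_chrom: str = "chr2"
    causal_gene_start: int = 10_000_000
    causal_gene_strand: str = "+"
    causal_cds_pos: int = 383  # 1-based position along the spliced CDS
    ref_allele: str = "G"
    alt_allele: str = "A"
    cm_per_mb: float = 1.0

    # planted gene geometry (bp): 5'UTR | CDS-exon1 | intron | CDS-exon2 | 3'UTR
    utr5_len: int = 50
    cds_exon1_len: int = 600
    intron_len: int = 300
    cds_exon2_len: int = 600
    utr3_len: int = 100

    def __post_init__(self):
        if self.causal_chrom not in dict(self.chromosomes):
            raise ValueError(f"causal_chrom {self.causal_chrom!r} not in chromosomes")
        if (self.cds_exon1_len + self.cds_exon2_len) % 3 != 0:
            raise ValueError("total CDS length must be divisible by 3")
        if not 1 <= self.causal_cds_pos <= self.cds_exon1_len:
            raise ValueError("causal CDS position must fall in the first CDS exon")
        if (self.ref_allele, self.alt_allele) != ("G", "A"):
            raise ValueError("the planted causal change is the G>A stop gain")
        if not 0 <= self.fixed_fraction <= 1:
            raise ValueError("fixed_fraction must be in [0, 1]")

    @property
    def gene_span(self) -> int:
        return (
            self.utr5_len
            + self.cds_exon1_len
            + self.intron_len
            + self.cds_exon2_len
            + self.utr3_len
        )


@dataclass
class Reference:
    """Reference genome plus the planted gene and the variant catalogue."""

    spec: GenomeSpec
    seqs: dict[str, np.ndarray]  # chrom -> ASCII bytes (uint8)
    gene: GeneModel
    variants: VariantTable  # includes is_fixed column
    cds_seq: str

    def chrom_seq(self, chrom: str) -> str:
        return self.seqs[chrom].tobytes().decode("ascii")

    @property
    def causal_index(self) -> int:
        return self.variants.causal_index()


def _random_cds(rng: np.random.Generator, n_codons: int, causal_codon_index: int) -> str:
    """Random CDS: ATG start, TGG at the causal codon, TAA stop, no internal stops."""
    sense = sorted(
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in _STOPS | {"ATG", "TGG"}
    )
    codons = [sense[i] for i in rng.integers(0, len(sense), size=n_codons)]
    codons[0] = "ATG"
    codons[causal_codon_index - 1] = "TGG"
    codons[-1] = "TAA"
    return "".join(codons)


def _plant_gene(spec: GenomeSpec) -> GeneModel:
    g0 = spec.causal_gene_start
    e1_start = g0
    e1_end = g0 + spec.utr5_len + spec.cds_exon1_len - 1
    cds1 = (g0 + spec.utr5_len, e1_end)
    e2_start = e1_end + spec.intron_len + 1
    e2_end = e2_start + spec.cds_exon2_len + spec.utr3_len - 1
    cds2 = (e2_start, e2_start + spec.cds_exon2_len - 1)
    chrom_len = dict(spec.chromosomes)[spec.causal_chrom]
    if e2_end > chrom_len:
        raise ValueError("causal gene does not fit on its chromosome")
    return GeneModel(
        gene_id="gene1",
        chrom=spec.causal_chrom,
        strand=spec.causal_gene_strand,
        exons=[(e1_start, e1_end), (e2_start, e2_end)],
        cds=[cds1, cds2],
    )


def build_reference(spec: GenomeSpec, seed: int | np.random.Generator) -> Reference:
    """Random reference genome carrying the WT allele everywhere, with the
    causal gene planted so that the codon covering ``causal_cds_pos`` is TGG
    and the G>A substitution there creates a TAG stop."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    seqs: dict[str, np.ndarray] = {}
    for chrom, length in spec.chromosomes:
        seqs[chrom] = _BASES[rng.integers(0, 4, size=length)].copy()

    gene = _plant_gene(spec)
    causal_codon = (spec.causal_cds_pos + 2) // 3
    n_codons = (spec.cds_exon1_len + spec.cds_exon2_len) // 3
    cds_seq = _random_cds(rng, n_codons, causal_codon)
    if cds_seq[spec.causal_cds_pos - 1] != spec.ref_allele:
        raise AssertionError("planted codon does not expose the reference allele")

    # splice the CDS into the chromosome on the coding strand
    chrom_arr = seqs[spec.causal_chrom]
    ordered = gene.cds if gene.strand == "+" else list(reversed(gene.cds))
    offset = 0
    for (s, e) in ordered:
        seg = cds_seq[offset : offset + (e - s + 1)]
        if gene.strand == "-":
            seg = revcomp(seg)
        chrom_arr[s - 1 : e] = np.frombuffer(seg.encode("ascii"), dtype=np.uint8)
        offset += e - s + 1

    causal_pos = gene.cds_to_genomic(spec.causal_cds_pos)
    # genomic alleles: on the minus strand the coding-strand G>A is a C>T
    if gene.strand == "+":
        g_ref, g_alt = spec.ref_allele, spec.alt_allele
    else:
        g_ref, g_alt = revcomp(spec.ref_allele), revcomp(spec.alt_allele)

    rows = []
    for chrom, length in spec.chromosomes:
        n = rng.poisson(length * spec.snp_density)
        pos = np.sort(rng.choice(length, size=min(n, length), replace=False)) + 1
        pos = pos[pos != causal_pos] if chrom == spec.causal_chrom else pos
        refs = seqs[chrom][pos - 1]
        # alt = uniform draw among the three non-reference bases
        ref_idx = np.searchsorted(_BASES, refs)
        alts = _BASES[(ref_idx + rng.integers(1, 4, size=len(pos))) % 4]
        fixed = rng.random(len(pos)) < spec.fixed_fraction
        for p, r, a, f in zip(pos, refs, alts, fixed):
            rows.append((chrom, int(p), chr(r), chr(a), False, bool(f)))
    rows.append((spec.causal_chrom, int(causal_pos), g_ref, g_alt, True, True))

    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "is_causal", "is_fixed"])
    variants = VariantTable(df, dict(spec.chromosomes))
    return Reference(spec=spec, seqs=seqs, gene=gene, variants=variants, cds_seq=cds_seq)


# ---------------------------------------------------------------------------
# meiosis and crosses
# ---------------------------------------------------------------------------


def make_gamete(
    parent: Individual,
    variants: VariantTable,
    rng: np.random.Generator,
    cm_per_mb: float = 1.0,
) -> np.ndarray:
    """One recombinant gamete under the Haldane model.

    Crossover count per chromosome ~ Poisson(map length in Morgans) at a
    uniform cM/Mb rate, breakpoints uniform, no interference; the
    recombinant fraction between loci d Morgans apart is (1 - e^(-2d))/2.
    """
    if parent.n_variants != len(variants):
        raise ValueError("parent haplotypes do not match the variant table")
    gamete = np.empty(len(variants), dtype=np.uint8)
    h = parent.haplotypes
    for chrom, sl in variants.chrom_slices():
        length_bp = variants.chrom_lengths[chrom]
        morgans = length_bp * cm_per_mb / 1e8
        n_xo = rng.poisson(morgans)
        breakpoints = np.sort(rng.uniform(0, length_bp, size=n_xo))
        start_phase = rng.integers(0, 2)
        pos = variants.positions[sl].astype(float)
        phase = (start_phase + np.searchsorted(breakpoints, pos)) % 2
        gamete[sl] = np.where(phase == 0, h[0, sl], h[1, sl])
    return gamete


def cross(
    dam: Individual,
    sire: Individual,
    n: int,
    variants: VariantTable,
    rng: np.random.Generator,
    cm_per_mb: float = 1.0,
    id_prefix: str = "F2",
    line: str = "F2",
) -> list[Individual]:
    """n offspring, each receiving one recombinant gamete per parent."""
    if dam.n_variants != sire.n_variants:
        raise ValueError("parents are defined over different variant lists")
    offspring = []
    for i in range(n):
        h0 = make_gamete(dam, variants, rng, cm_per_mb)
        h1 = make_gamete(sire, variants, rng, cm_per_mb)
        offspring.append(
            Individual(id=f"{id_prefix}_{i + 1:05d}", haplotypes=np.stack([h0, h1]), line=line)
        )
    return offspring


def phenotype_of(ind: Individual, causal_index: int, rule: str = "recessive") -> str:
    """Colour phenotype from the causal genotype.

    Under the recessive rule (the study's inheritance mode) an individual
    is yellow iff homozygous for the mutant allele; the dominant rule is
    kept only as a deliberate misconfiguration for contract tests.
    """
    if not 0 <= causal_index < ind.n_variants:
        raise ValueError("causal index outside the individual's variant list")
    g = int(ind.haplotypes[0, causal_index]) + int(ind.haplotypes[1, causal_index])
    if rule == "recessive":
        return "yellow" if g == 2 else "black"
    if rule == "dominant":
        return "yellow" if g >= 1 else "black"
    raise ValueError(f"unknown phenotype rule {rule!r}")


def founder(
    variants: VariantTable, line: str, rng: np.random.Generator, ind_id: str
) -> Individual:
    """A founder-line individual: homozygous for the line allele at fixed
    differences, Bernoulli(1/2) per haplotype at within-line segregating sites."""
    if line not in ("WT", "YM"):
        raise ValueError("founder line must be WT or YM")
    m = len(variants)
    fixed = variants.df["is_fixed"].to_numpy() if "is_fixed" in variants.df else np.ones(m, bool)
    base = np.uint8(0 if line == "WT" else 1)
    hap = np.empty((2, m), dtype=np.uint8)
    hap[:, :] = base
    noise = ~fixed
    hap[:, noise] = rng.integers(0, 2, size=(2, int(noise.sum())), dtype=np.uint8)
    return Individual(id=ind_id, haplotypes=hap, line=line)


def founder_pair_at_locus(
    dam_genotype: str, sire_genotype: str
) -> tuple[Individual, Individual, VariantTable]:
    """Parents defined over a single-locus variant table, for pure
    segregation-ratio simulations where only the causal genotype matters."""
    vt = VariantTable(
        pd.DataFrame(
            [("chrL", 500_000, "G", "A", True)],
            columns=["chrom", "pos", "ref", "alt", "is_causal"],
        ),
        {"chrL": 1_000_000},
    )
    gt_to_hap = {"AA": (0, 0), "Aa": (0, 1), "aa": (1, 1)}
    dam = Individual("dam", np.array([gt_to_hap[dam_genotype]]).T, line="F1")
    sire = Individual("sire", np.array([gt_to_hap[sire_genotype]]).T, line="F1")
    return dam, sire, vt


# ---------------------------------------------------------------------------
# pooled sequencing
# ---------------------------------------------------------------------------


def simulate_pool_counts(
    individuals: list[Individual],
    pool: PoolSpec,
    variants: VariantTable,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Pooled read counts per site.

    Total depth ~ Poisson(mean_coverage); each read samples one of the 2n
    pooled haplotypes uniformly and is miscalled with probability
    ``error_rate`` to a uniformly random other base (so 1/3 of errors land
    on the other modelled allele, 2/3 on a third allele). Returns a frame
    with ref/alt/other counts per variant.
    """
    if not individuals:
        raise ValueError("cannot pool an empty list of individuals")
    H = np.stack([ind.haplotypes for ind in individuals]).reshape(-1, len(variants))
    f = H.mean(axis=0)  # pooled alt-allele frequency per site
    e = pool.error_rate
    depth = rng.poisson(pool.mean_coverage, size=len(variants))
    other = rng.binomial(depth, 2 * e / 3)
    rest = depth - other
    p_alt = f * (1 - e) + (1 - f) * (e / 3)
    p_ref = (1 - f) * (1 - e) + f * (e / 3)
    with np.errstate(invalid="ignore"):
        cond = np.where(p_alt + p_ref > 0, p_alt / (p_alt + p_ref), 0.0)
    alt = rng.binomial(rest, cond)
    ref = rest - alt
    return pd.DataFrame(
        {
            "chrom": variants.chroms,
            "pos": variants.positions,
            f"{pool.pool_id.lower()}_ref": ref,
            f"{pool.pool_id.lower()}_alt": alt,
            f"{pool.pool_id.lower()}_other": other,
        }
    )


def genotype_panel(
    individuals: list[Individual],
    mean_depth: float,
    rng: np.random.Generator,
    min_callable_depth: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample genotype dosages and depths for the sequencing panel.

    DP ~ Poisson(mean_depth) per site and sample; a genotype is missing
    (-1) when fewer than ``min_callable_depth`` reads cover the site.
    """
    m = individuals[0].n_variants
    n = len(individuals)
    G = np.stack([ind.dosage() for ind in individuals], axis=1).astype(np.int8)
    DP = rng.poisson(mean_depth, size=(m, n)).astype(np.int32)
    G[DP < min_callable_depth] = -1
    return G, DP
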