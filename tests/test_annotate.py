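"""Variant-effect annotation: region classes, CDS coordinate arithmetic on
both strands, codon consequences and the full-protein translation oracle."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from recessmap.annotate import (
    annotate_candidates,
    annotate_variant,
    classify_region,
    codon_consequence,
    genomic_to_cds,
    parse_hgvs_c,
    parse_hgvs_p,
)
from recessmap.models import GeneModel, revcomp

# Small two-exon gene on a synthetic chromosome:
# 5'UTR 1..10 | CDS 11..40 | intron 41..60 | CDS 61..90 | 3'UTR 91..100


def _plus_gene_and_chrom():
    # 60 nt CDS: ATG start, 18 stop-free inner codons, TAA stop
    inner = "TGGCATCTTGAACGTATCGAACCTGTTAGAGGGTTCACCAAGCTGCATACG"  # 51 nt
    cds = "ATG" + inner + "TGG" + "TAA"
    assert len(cds) == 60 and len(cds) % 3 == 0
    chrom = (
        "T" * 10 + cds[:30] + "A" * 20 + cds[30:] + "C" * 10
    )
    gene = GeneModel(
        gene_id="g+", chrom="chrP", strand="+",
        exons=[(1, 40), (61, 100)], cds=[(11, 40), (61, 90)],
    )
    assert gene.cds_sequence(chrom) == cds
    return gene, chrom, cds


def _minus_gene_and_chrom():
    gene_p, chrom_p, cds = _plus_gene_and_chrom()
    L = len(chrom_p)
    chrom_m = revcomp(chrom_p)

    def flip(seg):
        s, e = seg
        return (L - e + 1, L - s + 1)

    gene_m = GeneModel(
        gene_id="g-", chrom="chrM", strand="-",
        exons=sorted(flip(x) for x in gene_p.exons),
        cds=sorted(flip(x) for x in gene_p.cds),
    )
    assert gene_m.cds_sequence(chrom_m) == cds
    return gene_m, chrom_m, cds


class TestClassifyRegion:
    def setup_method(self):
        self.gene, self.chrom, self.cds = _plus_gene_and_chrom()

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (5, "UTR"),        # 5' UTR
            (11, "CDS"),       # first CDS base, inclusive boundary
            (40, "CDS"),       # last base of CDS segment 1
            (50, "intronic"),
            (95, "UTR"),       # 3' UTR
            (500, "intergenic"),
        ],
    )
    def test_containment_classes(self, pos, expected):
        cls, _ = classify_region("chrP", pos, [self.gene])
        assert cls == expected

    def test_other_chromosome_is_intergenic(self):
        cls, gene = classify_region("chrX", 20, [self.gene])
        assert cls == "intergenic" and gene is None


class TestGeneModelValidation:
    def test_overlapping_cds_segments_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            GeneModel("g", "c", "+", exons=[(1, 100)], cds=[(1, 30), (25, 60)])

    def test_cds_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError, match="divisible"):
            GeneModel("g", "c", "+", exons=[(1, 100)], cds=[(1, 31)])

    def test_cds_must_lie_inside_exons(self):
        with pytest.raises(ValueError, match="inside an exon"):
            GeneModel("g", "c", "+", exons=[(1, 50)], cds=[(40, 60)])


class TestCoordinateMapping:
    def test_first_cds_base_plus_strand(self):
        gene, _, _ = _plus_gene_and_chrom()
        assert genomic_to_cds(11, gene) == 1

    def test_spliced_offset_across_intron(self):
        gene, _, _ = _plus_gene_and_chrom()
        assert genomic_to_cds(61, gene) == 31  # first base of second CDS exon

    def test_minus_strand_counts_from_three_prime_end(self):
        gene, _, _ = _minus_gene_and_chrom()
        # highest genomic CDS coordinate is CDS position 1 on minus strand
        top = max(e for _, e in gene.cds)
        assert genomic_to_cds(top, gene) == 1

    def test_exon1_offset_383_analogue(self, small_reference):
        gene = small_reference.gene
        cds1_start = gene.cds[0][0]
        assert gene.genomic_to_cds(cds1_start + 382) == 383

    def test_non_cds_position_rejected(self):
        gene, _, _ = _plus_gene_and_chrom()
        with pytest.raises(ValueError):
            genomic_to_cds(50, gene)

    @pytest.mark.parametrize("builder", [_plus_gene_and_chrom, _minus_gene_and_chrom])
    def test_round_trip_every_cds_base(self, builder):
        gene, _, _ = builder()
        for cds_pos in range(1, gene.cds_length + 1):
            g = gene.cds_to_genomic(cds_pos)
            assert gene.genomic_to_cds(g) == cds_pos


class TestCodonConsequence:
    def test_stop_gain_at_codon_128(self, small_reference):
        cds = small_reference.cds_seq
        eff = codon_consequence(383, "G", "A", cds)
        assert eff["codon_index"] == 128
        assert eff["ref_codon"] == "TGG" and eff["alt_codon"] == "TAG"
        assert eff["consequence"] == "stop_gain"
        assert eff["hgvs_c"] == "c.383G>A"
        assert eff["hgvs_p"] == "p.W128*"

    def test_synonymous_substitution(self):
        cds = "ATGGCG" + "TAA"
        eff = codon_consequence(6, "G", "A", cds)
        assert eff["consequence"] == "synonymous"
        assert eff["hgvs_p"] == "p.A2="

    def test_start_loss(self):
        cds = "ATGGCGTAA"
        eff = codon_consequence(1, "A", "G", cds)
        assert eff["consequence"] == "start_loss"

    def test_stop_loss(self):
        cds = "ATGGCGTAA"
        eff = codon_consequence(8, "A", "G", cds)  # TAA -> TGA? no: pos8 A>G = TGA stop
        # TAA with middle base G becomes TGA, still a stop -> synonymous stop
        assert eff["consequence"] == "synonymous"
        eff = codon_consequence(9, "A", "G", cds)  # TAA -> TAG, still stop
        assert eff["consequence"] == "synonymous"
        eff = codon_consequence(7, "T", "C", cds)  # TAA -> CAA (Gln), stop lost
        assert eff["consequence"] == "stop_loss"

    def test_reference_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            codon_consequence(2, "G", "A", "ATGTAA")

    @given(st.integers(1, 60), st.sampled_from("ACGT"))
    @settings(derandomize=True, max_examples=120)
    def test_codon_index_brackets_cds_position(self, cds_pos, alt):
        gene, chrom, cds = _plus_gene_and_chrom()
        ref = cds[cds_pos - 1]
        if ref == alt:
            return
        eff = codon_consequence(cds_pos, ref, alt, cds)
        ci = eff["codon_index"]
        assert 3 * ci - 2 <= cds_pos <= 3 * ci

    def test_full_protein_translation_oracle(self, small_reference, rng):
        """Predicted consequence class agrees with a direct translation of
        the mutated CDS, over 1000 random substitutions."""
        cds = small_reference.cds_seq
        ref_prot = str(Seq(cds).translate())
        for _ in range(1000):
            pos = int(rng.integers(1, len(cds) + 1))
            ref = cds[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            eff = codon_consequence(pos, ref, str(alt), cds)
            mut = cds[: pos - 1] + str(alt) + cds[pos:]
            alt_prot = str(Seq(mut).translate())
            ci = eff["codon_index"]
            if eff["consequence"] == "synonymous":
                assert alt_prot == ref_prot
            elif eff["consequence"] == "stop_gain":
                assert alt_prot[ci - 1] == "*" and ref_prot[ci - 1] != "*"
            elif eff["consequence"] == "missense":
                assert alt_prot[ci - 1] != ref_prot[ci - 1]
                assert alt_prot[ci - 1] != "*"
            elif eff["consequence"] == "stop_loss":
                assert ref_prot[ci - 1] == "*" and alt_prot[ci - 1] != "*"
            elif eff["consequence"] == "start_loss":
                assert ci == 1 and mut[:3] != "ATG"

    def test_strand_symmetry(self):
        """A gene and its reverse-complement placement give identical
        effect fields for corresponding variants."""
        gene_p, chrom_p, cds = _plus_gene_and_chrom()
        gene_m, chrom_m, _ = _minus_gene_and_chrom()
        L = len(chrom_p)
        rng = np.random.default_rng(6)
        for cds_pos in rng.integers(1, len(cds) + 1, size=40):
            cds_pos = int(cds_pos)
            gp = gene_p.cds_to_genomic(cds_pos)
            gm = gene_m.cds_to_genomic(cds_pos)
            assert gm == L - gp + 1
            ref_p = chrom_p[gp - 1]
            alt_p = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref_p]
            eff_p = annotate_variant("chrP", gp, ref_p, alt_p, [gene_p], {"chrP": chrom_p})
            eff_m = annotate_variant(
                "chrM", gm, revcomp(ref_p), revcomp(alt_p), [gene_m], {"chrM": chrom_m}
            )
            for f in ("cds_pos", "codon_index", "ref_codon", "alt_codon",
                      "consequence", "hgvs_c", "hgvs_p"):
                assert getattr(eff_p, f) == getattr(eff_m, f), f


class TestHgvsRoundTrip:
    def test_c_and_p_strings_regenerate_fields(self, small_reference):
        eff = codon_consequence(383, "G", "A", small_reference.cds_seq)
        assert parse_hgvs_c(eff["hgvs_c"]) == (383, "G", "A")
        aa, idx, sym = parse_hgvs_p(eff["hgvs_p"])
        assert (aa, idx, sym) == ("W", 128, "*")


class TestAnnotateCandidates:
    def test_planted_candidate_mix_counts(self, small_reference):
        """23 candidates planted as 1 CDS stop-gain + 9 intergenic +
        13 intronic are summarised exactly that way."""
        ref = small_reference
        gene = ref.gene
        chrom = gene.chrom
        causal = ref.variants.df.iloc[ref.causal_index]
        intron_start = ref.spec.causal_gene_start + ref.spec.utr5_len + ref.spec.cds_exon1_len
        rows = [
            {"chrom": chrom, "pos": int(causal["pos"]), "ref": "G", "alt": "A"}
        ]
        seq = ref.chrom_seq(chrom)
        for i in range(13):
            p = intron_start + 5 + i  # inside the intron
            rows.append({"chrom": chrom, "pos": p, "ref": seq[p - 1],
                         "alt": "A" if seq[p - 1] != "A" else "C"})
        for i in range(9):
            p = 1000 + i * 7  # far upstream of the gene
            rows.append({"chrom": chrom, "pos": p, "ref": seq[p - 1],
                         "alt": "A" if seq[p - 1] != "A" else "C"})
        table, summary = annotate_candidates(
            pd.DataFrame(rows), [gene], {chrom: seq}
        )
        assert summary == {"stop_gain": 1, "intronic": 13, "intergenic": 9}
        stop = table[table["consequence"] == "stop_gain"].iloc[0]
        assert stop["hgvs_c"] == "c.383G>A" and stop["hgvs_p"] == "p.W128*"

    def test_empty_candidate_list(self, small_reference):
        table, summary = annotate_candidates(
            pd.DataFrame(columns=["chrom", "pos", "ref", "alt"]),
            [small_reference.gene],
            {small_reference.gene.chrom: ""},
        )
        assert len(table) == 0 and summary == {}

    def test_unknown_chromosome_rejected(self, small_reference):
        gene = small_reference.gene
        cand = pd.DataFrame(
            [{"chrom": gene.chrom, "pos": gene.cds[0][0], "ref": "A", "alt": "G"}]
        )
        with pytest.raises(KeyError):
            annotate_candidates(cand, [gene], {"elsewhere": "ACGT"})
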