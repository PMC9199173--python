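"""CDS extraction, variant application, ORF integrity and rate arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusionscan.config import Parameters
from fusionscan.errors import CoordinateError, FusionscanError
from fusionscan.genes import GeneModel
from fusionscan.popfix import (
    Variant,
    apply_variants,
    birth_rate,
    extract_cds,
    fixation_frequency,
    ks_to_age,
    orf_intact,
    rate_from_age,
    read_population_vcf,
    weighted_rate,
)

PARAMS = Parameters()


def plus_gene(exons, gid="g"):
    return GeneModel(gid, "chr1", "+", exons[0][0], exons[-1][1], tuple(exons), gid)


class TestExtractCds:
    def test_single_exon_plus(self):
        chrom = "ATGAAATAGCCCCCC"
        assert extract_cds(plus_gene([(0, 9)]), chrom) == "ATGAAATAG"

    def test_two_exons_minus_strand(self):
        #       0123456789
        chrom = "AAACCCGGGTTT"
        exons_genomic = [(0, 3), (6, 9)]
        m = GeneModel("g", "chr1", "-", 0, 9, tuple(reversed(exons_genomic)), "g")
        # plus-strand splice AAA+GGG -> revcomp = CCCTTT
        assert extract_cds(m, chrom) == "CCCTTT"

    def test_exon_beyond_contig_rejected(self):
        with pytest.raises(CoordinateError):
            extract_cds(plus_gene([(0, 99)]), "ATG")


class TestApplyVariants:
    CHROM = "ATGTGGAAATAG" + "ACGT" * 5

    def gene(self):
        return plus_gene([(0, 12)])

    def test_stop_gain_substitution(self):
        # TGG codon -> TGA: premature in-frame stop
        out = apply_variants(self.gene(), self.CHROM, [Variant("chr1", 6, "G", "A")])
        assert out == "ATGTGAAAATAG"
        assert not orf_intact(out)

    def test_no_variants_identity(self):
        assert apply_variants(self.gene(), self.CHROM, []) == "ATGTGGAAATAG"

    def test_deletion_shortens_cds(self):
        out = apply_variants(self.gene(), self.CHROM, [Variant("chr1", 4, "TGG", "T")])
        assert out == "ATGTAAATAG"
        assert len(out) == 10

    def test_variant_outside_cds_ignored(self):
        out = apply_variants(self.gene(), self.CHROM, [Variant("chr1", 14, "C", "A")])
        assert out == "ATGTGGAAATAG"

    def test_reference_mismatch_names_site(self):
        with pytest.raises(FusionscanError, match="chr1:6"):
            apply_variants(self.gene(), self.CHROM, [Variant("chr1", 6, "T", "A")])

    def test_minus_strand_mapping(self):
        #        0         1
        #        0123456789012345
        chrom = "CTATTTCATGGGGGGG"
        # minus-strand CDS over [0,9): revcomp("CTATTTCAT") = ATGAAATAG
        m = GeneModel("g", "chr1", "-", 0, 9, ((0, 9),), "g")
        assert extract_cds(m, chrom) == "ATGAAATAG"
        # genomic T>C at pos 4 edits the complementary CDS base (A>G)
        out = apply_variants(m, chrom, [Variant("chr1", 4, "T", "C")])
        assert out == "ATGAAGTAG"

    @settings(max_examples=60, derandomize=True)
    @given(pos=st.integers(1, 12), alt=st.sampled_from("ACGT"))
    def test_apply_then_revert_restores_reference(self, pos, alt):
        ref = self.CHROM[pos - 1]
        if alt == ref:
            return
        gene = self.gene()
        forward = apply_variants(gene, self.CHROM, [Variant("chr1", pos, ref, alt)])
        # reverting on the edited chromosome restores the reference CDS
        edited_chrom = self.CHROM[: pos - 1] + alt + self.CHROM[pos:]
        back = apply_variants(gene, edited_chrom, [Variant("chr1", pos, alt, ref)])
        assert back == extract_cds(gene, self.CHROM)


class TestOrfIntact:
    @pytest.mark.parametrize(
        "cds,expected",
        [
            ("ATGAAATAG", True),  # stop only at terminus
            ("ATGTAAAAATAG", False),  # premature stop at codon 2
            ("ATGAAAAAAG", False),  # length 10: frameshift
            ("ATGANATAG", True),  # ambiguous codon not called as stop
            ("AT", False),
        ],
    )
    def test_cases(self, cds, expected):
        assert orf_intact(cds) is expected

    @settings(max_examples=80, derandomize=True)
    @given(
        n_codons=st.integers(2, 30),
        where=st.integers(0, 10 ** 6),
        indel_len=st.sampled_from([1, 2, 4, 5]),
    )
    def test_non_triplet_indel_always_breaks_frame(self, n_codons, where, indel_len):
        cds = "ATG" + "GCT" * (n_codons - 1)
        pos = where % (len(cds) - indel_len + 1)  # deletion fully inside the CDS
        mutated = cds[:pos] + cds[pos + indel_len :]
        assert not orf_intact(mutated)


class TestFixationFrequency:
    CHROM = "ATGTGGAAAGAATAG" + "A" * 10
    MODEL = plus_gene([(0, 15)])
    STOP = Variant("chr1", 6, "G", "A")  # TGG->TGA

    def matrix(self, carried, missing=()):
        row = []
        for j in range(10):
            if j in missing:
                row.append(-1)
            elif j in carried:
                row.append(2)
            else:
                row.append(0)
        return np.array([row])

    def test_no_disruption(self):
        res = fixation_frequency(
            self.MODEL, self.CHROM, [self.STOP], self.matrix(set()), "sp", PARAMS
        )
        assert res.frequency == 1.0 and res.fixed_in_species

    def test_three_of_ten_disrupted(self):
        res = fixation_frequency(
            self.MODEL, self.CHROM, [self.STOP], self.matrix({0, 1, 2}), "sp", PARAMS
        )
        assert res.frequency == pytest.approx(0.7)
        assert not res.fixed_in_species  # 0.7 < 0.80 threshold

    def test_all_disrupted(self):
        res = fixation_frequency(
            self.MODEL, self.CHROM, [self.STOP], self.matrix(set(range(10))), "sp",
            PARAMS,
        )
        assert res.frequency == 0.0

    def test_missing_genotypes_excluded_from_denominator(self):
        res = fixation_frequency(
            self.MODEL, self.CHROM, [self.STOP], self.matrix({0}, missing={9, 8}),
            "sp", PARAMS,
        )
        assert res.n_individuals == 8
        assert res.frequency == pytest.approx(7 / 8)

    def test_het_counts_unless_hom_only(self):
        gt = np.array([[1] + [0] * 9])
        res = fixation_frequency(
            self.MODEL, self.CHROM, [self.STOP], gt, "sp", PARAMS
        )
        assert res.n_fixed == 9
        res = fixation_frequency(
            self.MODEL, self.CHROM, [self.STOP], gt, "sp", PARAMS, hom_only=True
        )
        assert res.n_fixed == 10

    def test_zero_individuals_rejected(self):
        with pytest.raises(FusionscanError):
            fixation_frequency(
                self.MODEL, self.CHROM, [self.STOP], np.zeros((1, 0)), "sp", PARAMS
            )


class TestReadPopulationVcf:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "pop.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=100>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ti1\ti2\ti3\ti4\n"
            "chr1\t6\t.\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t./.\n"
        )
        samples, variants, gts = read_population_vcf(p)
        assert samples == ["i1", "i2", "i3", "i4"]
        assert variants == [Variant("chr1", 6, "G", "A")]
        assert gts.tolist() == [[0, 1, 2, -1]]

    def test_multiallelic_rejected(self, tmp_path):
        p = tmp_path / "pop.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=100>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ti1\n"
            "chr1\t6\t.\tG\tA,T\t.\tPASS\t.\tGT\t0/1\n"
        )
        with pytest.raises(FusionscanError, match="multi-allelic"):
            read_population_vcf(p)


class TestRates:
    def test_birth_rate_examples(self):
        assert birth_rate(252, 4, 1) == 63
        assert birth_rate(64, 4, 1) == 16
        assert birth_rate(0, 4, 1) == 0

    def test_weighted_rate_examples(self):
        assert round(weighted_rate(1, 1, 33, 43), 2) == 1.77
        assert weighted_rate(1, 1, 43, 43) == 2
        assert weighted_rate(2, 0, 1, 1) == 2

    def test_ks_to_age_examples(self):
        assert round(ks_to_age(1.5, 6.5e-9), 1) == 115.4
        assert ks_to_age(0, 6.5e-9) == 0
        assert round(ks_to_age(0.013, 6.5e-9), 1) == 1.0

    def test_rate_from_age_examples(self):
        assert round(rate_from_age(197, ks_to_age(1.5, 6.5e-9)), 1) == 1.7
        assert rate_from_age(0, 10) == 0
        assert rate_from_age(100, 50) == 2

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(FusionscanError):
            birth_rate(10, 0, 1)
        with pytest.raises(FusionscanError):
            ks_to_age(1.0, 0)
        with pytest.raises(FusionscanError):
            rate_from_age(1, 0)
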