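"""Origination typing, retro-fusion detection and TE intersection."""

import pytest
from intervaltree import IntervalTree

from fusionscan.classification import (
    classify_type,
    detect_retrofusion,
    locate_parents,
    te_overlap,
)
from fusionscan.config import Parameters
from fusionscan.errors import CoordinateError
from fusionscan.genes import GeneLocus, GeneModel, GeneTable
from fusionscan.homology import AlignmentHit, assort_hits

KB = 1000


def locus(gid, start, end, chrom="chr1"):
    return GeneLocus(gid, chrom, start, end, "+")


def parent(gid, start, end, chrom="chr1", spans=((0, 50),)):
    from fusionscan.classification import ParentLocus

    return ParentLocus(gid, locus(gid, start, end, chrom), tuple(spans))


class TestClassifyType:
    ADJ = 100.0  # kb

    def test_both_parents_same_region(self):
        fus = locus("f", 0, 2 * KB)
        p1 = parent("p1", 10 * KB, 12 * KB)
        p2 = parent("p2", 14 * KB, 16 * KB)
        oc = classify_type("f", fus, [p1, p2], {}, self.ADJ)
        assert (oc.type, oc.subpattern) == ("I", "A")

    def test_one_parent_adjacent_one_elsewhere(self):
        fus = locus("f", 0, 2 * KB)
        p1 = parent("p1", 10 * KB, 12 * KB)
        p2 = parent("p2", 0, 2 * KB, chrom="chr9")
        oc = classify_type("f", fus, [p1, p2], {}, self.ADJ)
        assert (oc.type, oc.subpattern) == ("I", "C")

    def test_both_parents_elsewhere(self):
        fus = locus("f", 0, 2 * KB)
        p1 = parent("p1", 500 * KB, 502 * KB)
        p2 = parent("p2", 900 * KB, 902 * KB)
        oc = classify_type("f", fus, [p1, p2], {}, self.ADJ)
        assert (oc.type, oc.subpattern) == ("I", "B")

    def test_single_surviving_parent(self):
        fus = locus("f", 0, 2 * KB)
        far = parent("p1", 500 * KB, 502 * KB)
        assert classify_type("f", fus, [far], {}, self.ADJ).subpattern == "D"
        near = parent("p1", 30 * KB, 32 * KB)
        oc = classify_type("f", fus, [near], {}, self.ADJ)
        assert (oc.type, oc.subpattern) == ("II", "E")

    def test_no_parents_synteny_split(self):
        fus = locus("f", 0, 2 * KB)
        co = {"other": [locus("x", 0, KB), locus("y", 5 * KB, 6 * KB)]}
        assert classify_type("f", fus, [], co, self.ADJ).subpattern == "G"
        apart = {"other": [locus("x", 0, KB), locus("y", 900 * KB, 901 * KB)]}
        oc = classify_type("f", fus, [], apart, self.ADJ)
        assert (oc.type, oc.subpattern) == ("III", "F")

    def test_type_partition(self):
        fus = locus("f", 0, 2 * KB)
        for parents, expected in (
            ([parent("a", 0, KB), parent("b", 0, KB)], "I"),
            ([parent("a", 0, KB)], "II"),
            ([], "III"),
        ):
            oc = classify_type("f", fus, parents, {}, self.ADJ)
            assert oc.type == expected
            assert oc.subpattern in {"I": "ABC", "II": "DE", "III": "FG"}[oc.type]


class TestLocateParents:
    def make_table(self):
        models = [
            GeneModel("fus", "chr1", "+", 0, 900, ((0, 900),), "fus.t1"),
            GeneModel("p1", "chr1", "+", 5000, 5300, ((5000, 5300),), "p1.t1"),
            GeneModel("p2", "chr1", "+", 9000, 9300, ((9000, 9300),), "p2.t1"),
            GeneModel("inside", "chr1", "+", 100, 400, ((100, 400),), "inside.t1"),
        ]
        return GeneTable(models)

    def call_with_short_hits(self, subjects):
        hits = [
            AlignmentHit("fus.t1", sid, 95.0, 50, a, b, 0, 50, 1e-40, 90.0, "sp")
            for sid, a, b in subjects
        ]
        return assort_hits("fus.t1", "sp", 100, hits, Parameters(), self_id="fus.t1")

    def test_two_parents_found(self):
        table = self.make_table()
        call = self.call_with_short_hits([("p1.t1", 0, 50), ("p2.t1", 55, 100)])
        parents = locate_parents(
            "fus", call, table, table.by_gene["fus"].locus
        )
        assert [p.gene_id for p in parents] == ["p1", "p2"]
        assert parents[0].query_spans == ((0, 50),)

    def test_self_gene_and_overlapping_gene_excluded(self):
        table = self.make_table()
        call = self.call_with_short_hits([("fus.t1", 0, 50), ("inside.t1", 55, 100)])
        # the self protein never enters short hits; 'inside' overlaps the locus
        assert (
            locate_parents("fus", call, table, table.by_gene["fus"].locus) == []
        )

    def test_unknown_subject_warns_and_is_skipped(self):
        table = self.make_table()
        call = self.call_with_short_hits([("ghost", 0, 50), ("p1.t1", 55, 100)])
        with pytest.warns(UserWarning, match="ghost"):
            parents = locate_parents(
                "fus", call, table, table.by_gene["fus"].locus
            )
        assert [p.gene_id for p in parents] == ["p1"]


def model(gid, exons, strand="+", chrom="chr1"):
    exons = tuple(exons)
    start = min(s for s, _ in exons)
    end = max(e for _, e in exons)
    ordered = tuple(sorted(exons, reverse=strand == "-"))
    return GeneModel(gid, chrom, strand, start, end, ordered, gid + ".t1")


class TestDetectRetrofusion:
    def test_multiexon_parent_inside_single_fusion_exon(self):
        # fusion: two exons of 300 nt CDS each; span sits inside exon 2
        fusion = model("f", [(0, 300), (450, 750)])
        par = model("p", [(0, 90), (200, 290), (400, 520)])  # 4 not needed; 3 exons
        flag = detect_retrofusion(fusion, par, (110, 190))  # nt 330..570
        assert flag.is_retro
        assert flag.fusion_span_exon_count == 1

    def test_single_exon_parent_never_retro(self):
        fusion = model("f", [(0, 600)])
        par = model("p", [(0, 300)])
        assert not detect_retrofusion(fusion, par, (0, 100)).is_retro

    def test_span_crossing_two_fusion_exons(self):
        # constructed coordinates: residues 90..110 -> nt 270..330 crosses the
        # junction at 300, so an intron interrupts the parental span
        fusion = model("f", [(0, 300), (450, 750)])
        par = model("p", [(0, 100), (200, 400)])
        flag = detect_retrofusion(fusion, par, (90, 110))
        assert flag.fusion_span_exon_count == 2
        assert not flag.is_retro

    def test_span_beyond_cds_rejected(self):
        fusion = model("f", [(0, 300)])
        par = model("p", [(0, 300)])
        with pytest.raises(CoordinateError):
            detect_retrofusion(fusion, par, (0, 101))

    def test_full_protein_maps_to_three_nt_per_residue(self):
        fusion = model("f", [(0, 333), (500, 1667)])
        assert fusion.cds_length == 3 * 500
        flag = detect_retrofusion(fusion, model("p", [(0, 300)]), (0, 500))
        assert flag.fusion_span_exon_count == 2

    def test_strand_flip_invariance(self):
        # mirror the plus-strand model on a 10 kb chromosome
        plus = model("f", [(1000, 1300), (1600, 1900)], "+")
        L = 10_000
        minus_exons = [(L - e, L - s) for s, e in [(1000, 1300), (1600, 1900)]]
        minus = model("f", minus_exons, "-")
        par = model("p", [(0, 90), (200, 290)])
        for span in [(5, 50), (95, 180), (120, 199)]:
            assert (
                detect_retrofusion(plus, par, span).is_retro
                == detect_retrofusion(minus, par, span).is_retro
            )


class TestTeOverlap:
    def tree(self, *ivals):
        t = IntervalTree()
        for s, e in ivals:
            t.addi(s, e)
        return {"chr1": t}

    def test_one_bp_overlap_counts(self):
        flags, n = te_overlap([locus("g", 99, 500)], self.tree((450, 600)))
        assert flags["g"] and n == 1

    def test_disjoint(self):
        flags, n = te_overlap([locus("g", 99, 500)], self.tree((600, 700)))
        assert not flags["g"] and n == 0

    def test_counts_over_multiple_loci(self):
        trees = self.tree((100, 200), (1000, 1100))
        loci = [locus("a", 150, 400), locus("b", 500, 800), locus("c", 1050, 1300)]
        flags, n = te_overlap(loci, trees)
        assert n == 2 and flags == {"a": True, "b": False, "c": True}

    def test_unknown_chromosome_warns_zero_overlap(self):
        with pytest.warns(UserWarning, match="chrX"):
            flags, n = te_overlap(
                [locus("g", 0, 100, chrom="chrX")], self.tree((0, 50))
            )
        assert n == 0
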