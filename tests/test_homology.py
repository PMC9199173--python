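"""Hit-table parsing and long/short copy assortment, incl. the greedy oracle."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusionscan.config import Parameters
from fusionscan.errors import CoordinateError, HitTableError
from fusionscan.homology import (
    AlignmentHit,
    assort_hits,
    copy_status_matrix,
    read_hit_table,
)

PARAMS = Parameters()


def hit(qs, qe, subject="s1", bits=100.0, pid=90.0, evalue=1e-50):
    """1-based inclusive residue span, like the file format."""
    return AlignmentHit(
        query_id="q",
        subject_id=subject,
        percent_identity=pid,
        aln_len=qe - qs + 1,
        q_start=qs - 1,
        q_end=qe,
        s_start=0,
        s_end=qe - qs + 1,
        e_value=evalue,
        bit_score=bits,
        subject_species="sp",
    )


class TestReadHitTable:
    def test_single_row(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("g1\th1\t95.0\t200\t5\t0\t1\t200\t1\t200\t1e-80\t400\n")
        hits = read_hit_table(p)
        assert len(hits) == 1
        assert (hits[0].q_start, hits[0].q_end) == (0, 200)
        assert hits[0].span == 200

    def test_reversed_coordinates_normalized(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("g1\th1\t95.0\t50\t0\t0\t60\t11\t1\t50\t1e-10\t90\n")
        (h,) = read_hit_table(p)
        assert (h.q_start, h.q_end) == (10, 60)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("")
        assert read_hit_table(p) == []

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("g1\th1\t95.0\t200\t5\t0\t1\t200\t1\t200\t1e-80\n")
        with pytest.raises(HitTableError, match=":1"):
            read_hit_table(p)

    def test_unknown_subject_species(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("g1\th1\t95.0\t200\t5\t0\t1\t200\t1\t200\t1e-80\t400\n")
        with pytest.raises(HitTableError, match="h1"):
            read_hit_table(p, species_of={})


class TestAssortHits:
    def test_single_long_hit(self):
        call = assort_hits("q", "sp", 100, [hit(5, 90)], PARAMS)
        assert call.has_long and not call.has_short and not call.short_hits

    def test_two_short_copies_cover_query(self):
        call = assort_hits(
            "q", "sp", 100, [hit(1, 45, "s1"), hit(50, 95, "s2")], PARAMS
        )
        assert not call.has_long
        assert call.has_short
        assert call.short_union_cov == pytest.approx(0.91)

    def test_overlapping_hits_reduce_to_longest(self):
        # brute-force-confirmed: only the 56-residue hit survives the filter
        hits = [hit(1, 45, "s1"), hit(40, 95, "s2"), hit(60, 80, "s3")]
        call = assort_hits("q", "sp", 100, hits, PARAMS)
        assert [(h.q_start, h.q_end) for h in call.short_hits] == [(39, 95)]
        assert not call.has_short  # a single copy is not fusion evidence

    def test_short_copy_boundary_is_strict(self):
        # 19% coverage excluded, leaving one copy -> no short-copy status
        call = assort_hits("q", "sp", 100, [hit(1, 19, "s1"), hit(25, 95, "s2")], PARAMS)
        assert len(call.short_hits) == 1
        assert not call.has_short

    def test_exactly_20_percent_excluded_and_80_not_long(self):
        call = assort_hits("q", "sp", 100, [hit(1, 20, "s1"), hit(21, 100, "s2")], PARAMS)
        # 20/100 == short_min_cov, excluded; 80/100 == long_cov, not long
        assert not call.has_long
        assert [(h.q_start, h.q_end) for h in call.short_hits] == [(20, 100)]

    def test_self_hit_not_a_short_candidate(self):
        hits = [hit(1, 100, subject="q"), hit(1, 45, "s1"), hit(50, 95, "s2")]
        call = assort_hits("q", "sp", 100, hits, PARAMS, self_id="q")
        assert call.has_long  # the self full-length hit
        assert all(h.subject_id != "q" for h in call.short_hits)
        assert call.has_short

    def test_distinct_subject_requirement(self):
        hits = [hit(1, 45, "p1"), hit(50, 95, "p1")]
        strict = assort_hits("q", "sp", 100, hits, PARAMS)
        assert not strict.has_short  # one parental gene, two spans
        per_span = assort_hits(
            "q", "sp", 100, hits, Parameters(distinct_subjects=False)
        )
        assert per_span.has_short

    def test_evalue_filter(self):
        call = assort_hits("q", "sp", 100, [hit(5, 90, evalue=1.0)], PARAMS)
        assert not call.has_long

    def test_hit_beyond_query_length_rejected(self):
        with pytest.raises(CoordinateError):
            assort_hits("q", "sp", 100, [hit(50, 120)], PARAMS)


def exhaustive_filter(hits):
    """Independent oracle: iteratively drop any hit overlapped by a longer
    surviving hit (ties resolved by the documented sort order)."""
    order = sorted(
        hits, key=lambda h: (-h.span, -h.bit_score, h.subject_id, h.q_start, h.q_end)
    )
    alive = list(order)
    changed = True
    while changed:
        changed = False
        for h in list(alive):
            rank_h = order.index(h)
            for g in alive:
                if g is h:
                    continue
                if h.overlaps(g) and order.index(g) < rank_h:
                    alive.remove(h)
                    changed = True
                    break
            if changed:
                break
    return sorted(alive, key=lambda h: h.q_start)


def random_hit_set(rng, qlen=100, max_hits=8):
    hits = []
    for i in range(rng.randint(1, max_hits)):
        a = rng.randint(1, qlen - 1)
        b = rng.randint(a, qlen)
        hits.append(
            hit(a, b, subject=f"s{rng.randint(1, 4)}", bits=rng.randint(20, 200))
        )
    return hits


class TestGreedyOracle:
    def test_greedy_equals_exhaustive_on_random_sets(self):
        rng = random.Random(1234)
        for _ in range(1000):
            hits = random_hit_set(rng)
            call = assort_hits("q", "sp", 100, hits, PARAMS)
            # long copies are assigned before the overlap filter runs
            remaining = [h for h in hits if h.coverage(100) <= PARAMS.long_cov]
            expect = [
                h
                for h in exhaustive_filter(remaining)
                if h.coverage(100) > PARAMS.short_min_cov
            ]
            assert list(call.short_hits) == expect


@st.composite
def hit_lists(draw):
    n = draw(st.integers(1, 8))
    out = []
    for i in range(n):
        a = draw(st.integers(1, 99))
        b = draw(st.integers(a, 100))
        out.append(hit(a, b, subject=f"s{draw(st.integers(1, 3))}",
                       bits=float(draw(st.integers(10, 300)))))
    return out


class TestProperties:
    @settings(max_examples=200, derandomize=True)
    @given(hits=hit_lists(), seed=st.integers(0, 2**16))
    def test_order_independence_and_coverage_bound(self, hits, seed):
        call = assort_hits("q", "sp", 100, hits, PARAMS)
        assert call.short_union_cov <= 1.0 + 1e-12
        shuffled = list(hits)
        random.Random(seed).shuffle(shuffled)
        assert assort_hits("q", "sp", 100, shuffled, PARAMS) == call

    @settings(max_examples=100, derandomize=True)
    @given(hits=hit_lists())
    def test_short_hits_pairwise_disjoint(self, hits):
        call = assort_hits("q", "sp", 100, hits, PARAMS)
        kept = call.short_hits
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert not kept[i].overlaps(kept[j])


class TestCopyStatusMatrix:
    def test_species_without_hits_all_absent(self):
        matrix = copy_status_matrix({"q": 100}, [], ["sp1", "sp2"], PARAMS)
        assert not matrix[("q", "sp1")].has_long
        assert not matrix[("q", "sp2")].has_short

    def test_self_full_hit_gives_long(self):
        h = AlignmentHit("q", "q", 100.0, 100, 0, 100, 0, 100, 1e-99, 200.0, "sp1")
        matrix = copy_status_matrix({"q": 100}, [h], ["sp1"], PARAMS)
        assert matrix[("q", "sp1")].has_long

    def test_unknown_query_rejected(self):
        h = AlignmentHit("mystery", "s", 90.0, 50, 0, 50, 0, 50, 1e-20, 80.0, "sp1")
        with pytest.raises(CoordinateError):
            copy_status_matrix({"q": 100}, [h], ["sp1"], PARAMS)
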