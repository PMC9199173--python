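"""Group presence, pattern calling, ortholog collapse and accounting."""

import itertools

import pytest

from fusionscan.config import Parameters
from fusionscan.detection import (
    ACCEPTED_PATTERNS,
    FusionCall,
    PresenceVector,
    call_fusion,
    collapse_orthologs,
    group_presence,
    shared_specific_table,
    topology_consistent,
)
from fusionscan.config import parse_newick
from fusionscan.errors import ConfigError
from fusionscan.homology import AlignmentHit

PARAMS = Parameters()


class TestGroupPresence:
    def test_single_species_group(self):
        assert group_presence({"A": True}, {"A"})
        assert not group_presence({"A": False}, {"A"})

    def test_one_absence_tolerated_in_larger_groups(self):
        flags = {"A": True, "B": True, "C": False}
        assert group_presence(flags, {"A", "B", "C"})
        flags["B"] = False
        assert not group_presence(flags, {"A", "B", "C"})

    def test_two_species_group_follows_the_stated_rule(self):
        # with <=1 absence tolerated, one of two present still scores present
        assert group_presence({"A": True, "B": False}, {"A", "B"})

    def test_missing_species_is_an_error(self):
        with pytest.raises(ConfigError):
            group_presence({"A": True}, {"A", "B"})

    def test_empty_group_is_an_error(self):
        with pytest.raises(ConfigError):
            group_presence({}, set())


class TestPatternSpace:
    def test_exactly_three_of_64_joint_patterns_accepted(self):
        combos = list(itertools.product([True, False], repeat=3))
        joint = [(L, S) for L in combos for S in combos]
        assert len(joint) == 64
        accepted = [ACCEPTED_PATTERNS.get(pair) for pair in joint]
        assert sum(1 for a in accepted if a) == 3
        assert set(ACCEPTED_PATTERNS.values()) == {
            "L110&S111",
            "L100&S111",
            "L100&S110",
        }


def vec(idx, L, S):
    to_flags = lambda s: tuple(c == "1" for c in s)
    return PresenceVector(idx, to_flags(L), to_flags(S))


class TestCallFusion:
    def test_accepted_pattern_reported_at_smallest_round(self):
        vectors = [vec(1, "111", "111"), vec(2, "100", "111"), vec(3, "100", "111")]
        call = call_fusion("q", "F", vectors)
        assert call.origination_round == 2
        assert call.pattern == "L100&S111"

    def test_all_long_everywhere_is_not_a_fusion(self):
        assert call_fusion("q", "F", [vec(1, "111", "111")]) is None

    def test_long_copy_in_outgroup_blocks_the_call(self):
        assert call_fusion("q", "F", [vec(1, "101", "111")]) is None

    def test_no_short_copies_is_not_a_fusion(self):
        assert call_fusion("q", "F", [vec(1, "100", "000")]) is None


def xhit(a, b, pid, length):
    return AlignmentHit(a, b, pid, length, 0, length, 0, length, 1e-90, 200.0, None)


def fc(qid, sp):
    return FusionCall(qid, sp, "L100&S111", 1, None)


class TestCollapse:
    def test_fully_linked_candidates_form_one_cluster(self):
        calls = [fc(f"g{i}", sp) for i, sp in enumerate("ABCD")]
        hits = [
            xhit(f"g{i}", f"g{j}", 99.0, 300)
            for i in range(4)
            for j in range(4)
            if i != j
        ]
        fset = collapse_orthologs(calls, hits, PARAMS, list("ABCD"))
        assert fset.n_unique == 1
        assert fset.clusters[0].species == frozenset("ABCD")
        assert fset.clusters[0].representative.query_id == "g0"

    def test_identity_boundary_is_strict(self):
        calls = [fc("g0", "A"), fc("g1", "B")]
        fset = collapse_orthologs(
            calls, [xhit("g0", "g1", 79.0, 300)], PARAMS, ["A", "B"]
        )
        assert fset.n_unique == 2
        # exactly 80 is not strictly greater either
        fset = collapse_orthologs(
            calls, [xhit("g0", "g1", 80.0, 300)], PARAMS, ["A", "B"]
        )
        assert fset.n_unique == 2

    def test_minimum_aligned_length(self):
        calls = [fc("g0", "A"), fc("g1", "B")]
        fset = collapse_orthologs(
            calls, [xhit("g0", "g1", 95.0, 99)], PARAMS, ["A", "B"]
        )
        assert fset.n_unique == 2

    def test_transitive_closure_chain(self):
        calls = [fc("a", "A"), fc("b", "B"), fc("c", "C")]
        hits = [xhit("a", "b", 85.0, 200), xhit("b", "c", 85.0, 200),
                xhit("a", "c", 40.0, 200)]
        fset = collapse_orthologs(calls, hits, PARAMS, ["A", "B", "C"])
        assert fset.n_unique == 1
        assert len(fset.clusters[0].members) == 3

    def test_components_equal_bruteforce_transitive_closure(self):
        import random

        rng = random.Random(7)
        for _ in range(50):
            n = rng.randint(2, 10)
            calls = [fc(f"n{i}", f"S{i}") for i in range(n)]
            hits = []
            edges = set()
            for _e in range(rng.randint(0, n * 2)):
                i, j = rng.randint(0, n - 1), rng.randint(0, n - 1)
                if i != j:
                    hits.append(xhit(f"n{i}", f"n{j}", 95.0, 200))
                    edges.add(frozenset((i, j)))
            fset = collapse_orthologs(
                calls, hits, PARAMS, [f"S{i}" for i in range(n)]
            )
            # oracle: Floyd-Warshall transitive closure of the edge relation
            reach = [[i == j for j in range(n)] for i in range(n)]
            for e in edges:
                i, j = tuple(e)
                reach[i][j] = reach[j][i] = True
            for k in range(n):
                for i in range(n):
                    for j in range(n):
                        reach[i][j] = reach[i][j] or (reach[i][k] and reach[k][j])
            expected = {
                frozenset(f"n{j}" for j in range(n) if reach[i][j]) for i in range(n)
            }
            got = {frozenset(c.query_id for c in cl.members) for cl in fset.clusters}
            assert got == expected

    def test_collapse_is_idempotent(self):
        calls = [fc("a", "A"), fc("b", "B")]
        hits = [xhit("a", "b", 95.0, 200)]
        once = collapse_orthologs(calls, hits, PARAMS, ["A", "B"])
        again = collapse_orthologs(once.calls(), hits, PARAMS, ["A", "B"])
        assert {frozenset(c.query_id for c in cl.members) for cl in once.clusters} == {
            frozenset(c.query_id for c in cl.members) for cl in again.clusters
        }


class TestAccounting:
    def test_shared_specific_counts(self):
        calls = {
            "c1": [fc("a1", "A")],
            "c2": [fc("a2", "A")],
            "c3": [fc("a3", "A"), fc("b3", "B")],
            "c4": [fc(s.lower() + "4", s) for s in "ABCD"],
        }
        hits = []
        for members in calls.values():
            for x in members:
                for y in members:
                    if x is not y:
                        hits.append(xhit(x.query_id, y.query_id, 99.0, 300))
        all_calls = [c for v in calls.values() for c in v]
        fset = collapse_orthologs(all_calls, hits, PARAMS, list("ABCD"))
        table = shared_specific_table(fset, list("ABCD"))
        assert table["specific"]["A"] == 2
        assert table["shared_by"] == {2: 1, 4: 1}
        assert table["total"] == 4

    def test_empty_set(self):
        fset = collapse_orthologs([], [], PARAMS, ["A"])
        table = shared_specific_table(fset, ["A"])
        assert table["total"] == 0
        assert table["specific"] == {"A": 0}


class TestTopologyConsistent:
    PHYLO = parse_newick("((jap,ind),(bar,gla));")
    FOCUS = ["jap", "ind", "bar", "gla"]

    @pytest.mark.parametrize(
        "species,expected",
        [
            ({"bar", "gla"}, True),
            ({"ind", "bar"}, False),
            ({"jap", "ind", "bar", "gla"}, True),
            ({"jap"}, True),
        ],
    )
    def test_clade_membership(self, species, expected):
        assert topology_consistent(species, self.PHYLO, self.FOCUS) is expected
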