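"""Presence vectors, fusion calls, ortholog collapse and accounting.

Per detection round the long-copy (L) and short-copy (S) status of a query is
summarized over the in-, mid- and out-group as two 3-bit vectors; a group of
two or more species tolerates absence in at most ``max_group_absent``
members (default one), absorbing assembly and annotation imperfections.
Of the 64 joint (L, S) combinations exactly three are accepted as fusion
evidence:

* ``L-110 & S-111`` — fused gene in in- and mid-group, parents everywhere;
* ``L-100 & S-111`` — fused gene only in the in-group, parents everywhere;
* ``L-100 & S-110`` — fused gene only in the in-group, parents in in- and
  mid-group.

The out-group never carries the long copy: that would instead imply a gene
fission or an older origin.  When several rounds match, the smallest (most
recent in-group) is reported.  Calls made in different focus species are
collapsed into ortholog clusters (identity > ``ortholog_identity`` over
≥ ``ortholog_min_len`` aligned columns, transitively closed) so each fusion
event is counted once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .config import GroupRound, Parameters, Phylogeny
from .errors import ConfigError
from .genes import GeneLocus
from .homology import AlignmentHit, CopyCall

__all__ = [
    "ACCEPTED_PATTERNS",
    "PresenceVector",
    "FusionCall",
    "OrthologCluster",
    "FusionSet",
    "group_presence",
    "presence_vectors",
    "call_fusion",
    "detect_focus_species",
    "collapse_orthologs",
    "shared_specific_table",
    "topology_consistent",
]

Flags = tuple[bool, bool, bool]

#: The three accepted (L, S) joint patterns, keyed by (L flags, S flags).
ACCEPTED_PATTERNS: dict[tuple[Flags, Flags], str] = {
    ((True, True, False), (True, True, True)): "L110&S111",
    ((True, False, False), (True, True, True)): "L100&S111",
    ((True, False, False), (True, True, False)): "L100&S110",
}


def group_presence(
    flags: Mapping[str, bool], group: Iterable[str], max_absent: int = 1
) -> bool:
    """Presence of a copy in a species group.

    A single-species group requires that species; a larger group tolerates
    at most *max_absent* missing members.
    """
    members = sorted(group)
    if not members:
        raise ConfigError("group_presence called with an empty group")
    try:
        absent = sum(1 for s in members if not flags[s])
    except KeyError as exc:
        raise ConfigError(f"species {exc.args[0]!r} missing from presence flags")
    if len(members) == 1:
        return absent == 0
    return absent <= max_absent


@dataclass(frozen=True)
class PresenceVector:
    """L and S group-presence flags (in, mid, out) for one round."""

    round_index: int
    L: Flags
    S: Flags

    def pattern(self) -> str | None:
        """Accepted pattern label, or None."""
        return ACCEPTED_PATTERNS.get((self.L, self.S))

    def __str__(self) -> str:  # e.g. "L-110 S-111"
        fmt = lambda f: "".join("1" if x else "0" for x in f)
        return f"L-{fmt(self.L)} S-{fmt(self.S)}"


def presence_vectors(
    query_id: str,
    matrix: Mapping[tuple[str, str], CopyCall],
    rounds: Sequence[GroupRound],
    max_absent: int = 1,
) -> list[PresenceVector]:
    """One (L, S) vector per round from the per-species copy-status matrix."""
    species = rounds[0].all_species() if rounds else frozenset()
    long_flags = {s: matrix[(query_id, s)].has_long for s in species}
    short_flags = {s: matrix[(query_id, s)].has_short for s in species}
    vectors = []
    for rnd in rounds:
        L = tuple(
            group_presence(long_flags, grp, max_absent)
            for grp in (rnd.in_group, rnd.mid_group, rnd.out_group)
        )
        S = tuple(
            group_presence(short_flags, grp, max_absent)
            for grp in (rnd.in_group, rnd.mid_group, rnd.out_group)
        )
        vectors.append(PresenceVector(rnd.index, L, S))  # type: ignore[arg-type]
    return vectors


@dataclass(frozen=True)
class FusionCall:
    """A query accepted as a fusion gene in one focus species."""

    query_id: str
    focus_species: str
    pattern: str
    origination_round: int
    locus: GeneLocus | None = None


def call_fusion(
    query_id: str,
    focus_species: str,
    vectors: Sequence[PresenceVector],
    locus: GeneLocus | None = None,
) -> FusionCall | None:
    """Return a call at the smallest round matching an accepted pattern."""
    for vec in sorted(vectors, key=lambda v: v.round_index):
        pattern = vec.pattern()
        if pattern is not None:
            return FusionCall(query_id, focus_species, pattern, vec.round_index, locus)
    return None


def detect_focus_species(
    focus: str,
    matrix: Mapping[tuple[str, str], CopyCall],
    rounds: Sequence[GroupRound],
    params: Parameters,
    loci: Mapping[str, GeneLocus] | None = None,
    gene_of: Mapping[str, str] | None = None,
) -> list[FusionCall]:
    """Scan every query of one focus species for fusion evidence.

    *loci* (keyed by gene id) and *gene_of* (protein→gene) attach a genomic
    locus to each call when available.
    """
    queries = sorted({q for (q, _s) in matrix})
    calls = []
    for query in queries:
        vectors = presence_vectors(query, matrix, rounds, params.max_group_absent)
        locus = None
        if loci is not None:
            gid = gene_of.get(query, query) if gene_of else query
            locus = loci.get(gid)
        call = call_fusion(query, focus, vectors, locus)
        if call is not None:
            calls.append(call)
    return calls


@dataclass(frozen=True)
class OrthologCluster:
    cluster_id: int
    members: tuple[FusionCall, ...]
    representative: FusionCall
    species: frozenset[str]


@dataclass(frozen=True)
class FusionSet:
    """Fusion calls partitioned into cross-species ortholog clusters."""

    clusters: tuple[OrthologCluster, ...]

    @property
    def n_unique(self) -> int:
        return len(self.clusters)

    def calls(self) -> list[FusionCall]:
        return [c for cl in self.clusters for c in cl.members]


def collapse_orthologs(
    calls: Sequence[FusionCall],
    cross_hits: Iterable[AlignmentHit],
    params: Parameters,
    species_priority: Sequence[str],
) -> FusionSet:
    """Cluster calls whose proteins align at > ``ortholog_identity`` percent
    identity over ≥ ``ortholog_min_len`` columns (connected components, i.e.
    transitive closure).  The representative is the member from the
    highest-priority species, ties broken by gene id.
    """
    by_id = {c.query_id: c for c in calls}
    graph = nx.Graph()
    graph.add_nodes_from(by_id)
    for h in cross_hits:
        if h.query_id in by_id and h.subject_id in by_id and h.query_id != h.subject_id:
            if (
                h.percent_identity > params.ortholog_identity
                and h.aln_len >= params.ortholog_min_len
            ):
                graph.add_edge(h.query_id, h.subject_id)
    priority = {sp: i for i, sp in enumerate(species_priority)}
    clusters = []
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for i, comp in enumerate(components, start=1):
        members = tuple(sorted((by_id[q] for q in comp), key=lambda c: c.query_id))
        rep = min(
            members,
            key=lambda c: (priority.get(c.focus_species, len(priority)), c.query_id),
        )
        clusters.append(
            OrthologCluster(
                cluster_id=i,
                members=members,
                representative=rep,
                species=frozenset(c.focus_species for c in members),
            )
        )
    return FusionSet(clusters=tuple(clusters))


def shared_specific_table(
    fusion_set: FusionSet, focus_species: Sequence[str]
) -> dict[str, object]:
    """Shared/specific accounting of ortholog clusters.

    Returns ``specific`` (clusters found in exactly one focus species, keyed
    by species), ``shared_by`` (cluster counts keyed by number of sharing
    species ≥ 2), ``by_combination`` (counts keyed by the exact species
    combination) and ``total``.
    """
    specific = {sp: 0 for sp in focus_species}
    shared_by: dict[int, int] = {}
    by_combination: dict[tuple[str, ...], int] = {}
    for cl in fusion_set.clusters:
        combo = tuple(sorted(cl.species))
        by_combination[combo] = by_combination.get(combo, 0) + 1
        if len(cl.species) == 1:
            specific[combo[0]] = specific.get(combo[0], 0) + 1
        else:
            shared_by[len(cl.species)] = shared_by.get(len(cl.species), 0) + 1
    return {
        "specific": specific,
        "shared_by": dict(sorted(shared_by.items())),
        "by_combination": dict(sorted(by_combination.items())),
        "total": fusion_set.n_unique,
    }


def topology_consistent(
    species_set: Iterable[str], phylogeny: Phylogeny, focus_species: Iterable[str]
) -> bool:
    """Whether a cluster's species set matches a clade of the tree.

    True iff the set equals the focus-species restriction of some clade's
    leaf set — the single-origination, no-loss explanation of the sharing.
    """
    target = frozenset(species_set)
    if not target:
        return False
    focus = frozenset(focus_species)
    if not target <= phylogeny.leaf_labels:
        raise ConfigError(f"unknown species in cluster: {sorted(target - phylogeny.leaf_labels)}")
    for clade in phylogeny.clade_leaf_sets():
        if clade & focus == target:
            return True
    return False
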