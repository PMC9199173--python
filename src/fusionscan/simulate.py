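"""Seeded desk-scale simulator with planted fusion events and ground truth.

The generator emulates the data regime the detector consumes: several
closely related annotated proteomes relaxed along a known rooted phylogeny,
tabular protein alignment hits consistent with the known homology, gene
models on synthetic chromosomes, population variant tables with a controlled
fraction of ORF-disrupting alleles, and three-tissue FPKM profiles.

Proteins evolve by i.i.d. substitutions only (no indels), which keeps the
true homologous spans exact so hits can be synthesized without running an
aligner.  A planted fusion on a chosen branch concatenates two background
("parental") proteins at that node; parents can be deleted in selected
descendant species to create Type II/III origination cases, and a retro
event writes the fusion as a single-CDS-exon gene from a multi-exon parent.
Every output is a pure function of the plan (including its seed).

Planted events must remain detectable under the detector's own group rules:
a parent deleted in the focus species is only tolerated when the event's
clade has at least one other carrier, so plans that would be invisible by
construction are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from . import detection
from .config import ControlConfig, Phylogeny, parse_newick
from .errors import PlanError
from .genes import GeneModel
from .homology import AlignmentHit, write_hit_table

__all__ = [
    "PlantedFusion",
    "SimulationPlan",
    "TruthEntry",
    "Truth",
    "SimulatedBundle",
    "default_tree",
    "default_plan",
    "simulate_bundle",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

# one fixed codon per amino acid; several are a single substitution away
# from a stop codon, which the population simulator exploits
CODON = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTA",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGA",
    "S": "TCA", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAC",
}
STOP_CODONS = ("TAA", "TAG", "TGA")
INTRON_LEN = 150
PLACEMENTS = ("dispersed", "same_region", "near_one")
EXPRESSION_MODES = ("parental_like", "novel", "silent")


@dataclass(frozen=True)
class PlantedFusion:
    """One planted fusion event.

    ``branch`` is the leaf set of the clade on whose stem the fusion arises
    (a single species for a species-specific event).  ``drop_in`` names the
    carrier species in which a parent flagged ``keep_parent_* = False`` is
    absent from the annotation.  ``placement`` controls genomic position and
    hence the expected origination sub-pattern: ``dispersed`` → B/D/F,
    ``same_region`` → A/G, ``near_one`` → C/E.
    """

    name: str
    branch: frozenset[str]
    parent_a: int
    parent_b: int
    keep_parent_a: bool = True
    keep_parent_b: bool = True
    retro: bool = False
    placement: str = "dispersed"
    expression_mode: str = "novel"
    drop_in: frozenset[str] = frozenset()


@dataclass
class SimulationPlan:
    """Everything a simulation needs; outputs are a pure function of it."""

    newick: str
    focus_species: tuple[str, ...]
    outgroup_species: tuple[str, ...]
    n_background_genes: int = 60
    protein_length_range: tuple[int, int] = (80, 240)
    branch_sub_prob: float = 0.02
    events: tuple[PlantedFusion, ...] = ()
    n_individuals: int = 30
    disruption_prob: float = 0.1
    noise_hit_rate: float = 0.0
    seed: int = 0
    intergenic_gap: int = 20_000
    near_gap: int = 2_000
    adjacency_kb: float = 10.0
    tissues: tuple[str, ...] = ("root", "leaf", "panicle")
    write_genomes: str = "focus"  # "focus" | "all" | "none"

    def __post_init__(self) -> None:
        self.phylogeny: Phylogeny = parse_newick(self.newick)
        leaves = self.phylogeny.leaf_labels
        if not set(self.focus_species) <= leaves or not set(self.outgroup_species) <= leaves:
            raise PlanError("focus/outgroup species must be leaves of the tree")
        lo, hi = self.protein_length_range
        if not (10 <= lo <= hi):
            raise PlanError("protein_length_range must satisfy 10 <= lo <= hi")
        if not 0.0 <= self.branch_sub_prob < 0.5:
            raise PlanError("branch_sub_prob must be in [0, 0.5)")
        if self.write_genomes not in ("focus", "all", "none"):
            raise PlanError("write_genomes must be 'focus', 'all' or 'none'")
        clades = set(self.phylogeny.clade_leaf_sets())
        used_parents: set[int] = set()
        names: set[str] = set()
        normalized = []
        for ev in self.events:
            if ev.name in names:
                raise PlanError(f"duplicate event name {ev.name!r}")
            names.add(ev.name)
            if ev.placement not in PLACEMENTS:
                raise PlanError(f"{ev.name}: unknown placement {ev.placement!r}")
            if ev.expression_mode not in EXPRESSION_MODES:
                raise PlanError(f"{ev.name}: unknown expression mode")
            if ev.branch not in clades:
                raise PlanError(f"{ev.name}: branch {sorted(ev.branch)} is not a clade")
            if ev.branch & set(self.outgroup_species):
                raise PlanError(f"{ev.name}: carriers may not include out-group species")
            for p in (ev.parent_a, ev.parent_b):
                if not 0 <= p < self.n_background_genes:
                    raise PlanError(f"{ev.name}: parent index {p} out of range")
                if p in used_parents:
                    raise PlanError(f"{ev.name}: parent {p} reused across events")
                used_parents.add(p)
            if ev.parent_a == ev.parent_b:
                raise PlanError(f"{ev.name}: parents must be distinct genes")
            drop = ev.drop_in
            if not ev.keep_parent_a or not ev.keep_parent_b:
                if not drop:
                    focus_carriers = [s for s in self.focus_species if s in ev.branch]
                    if not focus_carriers:
                        raise PlanError(
                            f"{ev.name}: parent loss requires a focus carrier"
                        )
                    drop = frozenset({focus_carriers[0]})
                if not drop <= ev.branch:
                    raise PlanError(f"{ev.name}: drop_in must be carrier species")
                if len(ev.branch) - len(drop) < 1:
                    raise PlanError(
                        f"{ev.name}: a parent lost in every carrier makes the "
                        "event undetectable under the group-presence rules"
                    )
                both_lost = not ev.keep_parent_a and not ev.keep_parent_b
                if ev.placement == "near_one" and both_lost:
                    raise PlanError(f"{ev.name}: near_one needs a surviving parent")
                if ev.placement == "same_region" and not both_lost and (
                    not ev.keep_parent_a or not ev.keep_parent_b
                ):
                    raise PlanError(
                        f"{ev.name}: same_region needs both parents kept or both lost"
                    )
            if ev.retro and not ev.keep_parent_a:
                raise PlanError(f"{ev.name}: retro events must keep parent_a")
            normalized.append(dataclasses.replace(ev, drop_in=drop))
        self.events = tuple(normalized)

    # -- helpers --------------------------------------------------------

    @property
    def species_order(self) -> tuple[str, ...]:
        """Focus species first (given order), then remaining leaves in
        newick order, out-group species last."""
        tree_order = [
            leaf.taxon.label for leaf in self.phylogeny.tree.leaf_node_iter()
        ]
        out = set(self.outgroup_species)
        mids = [s for s in tree_order if s not in out and s not in self.focus_species]
        return tuple(self.focus_species) + tuple(mids) + tuple(self.outgroup_species)

    def parent_present(self, ev: PlantedFusion, which: str, species: str) -> bool:
        keep = ev.keep_parent_a if which == "a" else ev.keep_parent_b
        return keep or species not in ev.drop_in

    def bg_present(self, index: int, species: str) -> bool:
        for ev in self.events:
            if ev.parent_a == index and not self.parent_present(ev, "a", species):
                return False
            if ev.parent_b == index and not self.parent_present(ev, "b", species):
                return False
        return True


def default_tree() -> str:
    """A ten-species study-shaped tree: four focus species in two sister
    pairs, three laddered mid-group species, three out-group species."""
    return "((((((A1,A2),(A3,A4)),M1),M2),M3),(O1,(O2,O3)));"


def default_plan(
    seed: int = 0,
    n_background_genes: int = 60,
    events: Sequence[PlantedFusion] | None = None,
    **overrides,
) -> SimulationPlan:
    """The canonical desk-scale plan: ten species, four focus, three fixed
    out-group, with a representative mix of planted events unless an
    explicit event list is given."""
    if events is None:
        events = [
            # species-specific Type I, dispersed (→ B), parental-like expression
            PlantedFusion(
                "fusb", frozenset({"A1"}), 0, 1,
                placement="dispersed", expression_mode="parental_like",
            ),
            # species-specific Type I in the same region (→ A)
            PlantedFusion(
                "fusa", frozenset({"A2"}), 2, 3,
                placement="same_region", expression_mode="novel",
            ),
            # Type I near one parent (→ C), shared by the A1/A2 pair
            PlantedFusion(
                "fusc", frozenset({"A1", "A2"}), 4, 5,
                placement="near_one", expression_mode="novel",
            ),
            # Type II: parent_b lost in A1 (→ D)
            PlantedFusion(
                "fusd", frozenset({"A1", "A2"}), 6, 7,
                keep_parent_b=False, placement="dispersed",
                expression_mode="parental_like",
            ),
            # Type II adjacent to the surviving parent (→ E)
            PlantedFusion(
                "fuse", frozenset({"A3", "A4"}), 8, 9,
                keep_parent_b=False, placement="near_one",
                expression_mode="novel",
            ),
            # Type III, parents lost in A3, co-located elsewhere (→ G)
            PlantedFusion(
                "fusg", frozenset({"A3", "A4"}), 10, 11,
                keep_parent_a=False, keep_parent_b=False,
                placement="same_region", expression_mode="silent",
            ),
            # Type III dispersed (→ F)
            PlantedFusion(
                "fusf", frozenset({"A1", "A2", "A3", "A4"}), 12, 13,
                keep_parent_a=False, keep_parent_b=False,
                placement="dispersed", expression_mode="novel",
                drop_in=frozenset({"A4"}),
            ),
            # retro-fusion: multi-exon parent_a retroposed into one exon
            PlantedFusion(
                "fusr", frozenset({"A1"}), 14, 15,
                retro=True, placement="dispersed",
                expression_mode="parental_like",
            ),
        ]
    return SimulationPlan(
        newick=default_tree(),
        focus_species=("A1", "A2", "A3", "A4"),
        outgroup_species=("O1", "O2", "O3"),
        n_background_genes=n_background_genes,
        events=tuple(events),
        seed=seed,
        **overrides,
    )


# ---------------------------------------------------------------------------
# Truth


@dataclass
class TruthEntry:
    """Ground truth of one planted event, per focus species."""

    name: str
    carriers: frozenset[str]
    fusion_ids: dict[str, str]  # species -> gene id
    parent_ids: dict[str, tuple[str, ...]]  # species -> parent gene ids present
    parent_len_a: int
    parent_len_b: int
    retro: bool
    expected_round: dict[str, int | None]
    expected_pattern: dict[str, str | None]
    expected_type: dict[str, str]  # focus carriers only
    expected_subpattern: dict[str, str]
    expected_expression: dict[str, str | None]  # focus carriers only
    fixation_freq: dict[str, float] = field(default_factory=dict)


@dataclass
class Truth:
    """Ground truth for a simulated bundle."""

    entries: list[TruthEntry]
    te_counts: dict[str, int] = field(default_factory=dict)
    te_flagged: dict[str, frozenset[str]] = field(default_factory=dict)

    def expected_calls(self, focus: str) -> dict[str, int]:
        """Expected fusion query ids and origination rounds in one species."""
        out = {}
        for e in self.entries:
            if focus in e.carriers and e.expected_round.get(focus) is not None:
                out[e.fusion_ids[focus]] = e.expected_round[focus]
        return out

    def entry(self, name: str) -> TruthEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def write_tsv(self, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "event\tspecies\tfusion_id\texpected_round\texpected_pattern\t"
                "expected_type\texpected_subpattern\tretro\t"
                "expected_expression\tfixation_freq\n"
            )
            for e in self.entries:
                for sp in sorted(e.carriers):
                    fh.write(
                        "\t".join(
                            [
                                e.name,
                                sp,
                                e.fusion_ids[sp],
                                str(e.expected_round.get(sp, "")),
                                str(e.expected_pattern.get(sp, "")),
                                e.expected_type.get(sp, ""),
                                e.expected_subpattern.get(sp, ""),
                                str(int(e.retro)),
                                str(e.expected_expression.get(sp, "")),
                                f"{e.fixation_freq[sp]:.4f}"
                                if sp in e.fixation_freq
                                else "",
                            ]
                        )
                        + "\n"
                    )


def _expected_call(
    plan: SimulationPlan, ev: PlantedFusion, focus: str
) -> tuple[int | None, str | None]:
    """Round/pattern the detector should report, derived from truth
    presence/absence flags and the group-presence rules alone."""
    from .config import build_group_rounds

    rounds = build_group_rounds(plan.phylogeny, focus, plan.outgroup_species)
    species = rounds[0].all_species()
    long_flags = {s: s in ev.branch for s in species}
    short_flags = {
        s: plan.parent_present(ev, "a", s) and plan.parent_present(ev, "b", s)
        for s in species
    }
    for rnd in rounds:
        L = tuple(
            detection.group_presence(long_flags, g)
            for g in (rnd.in_group, rnd.mid_group, rnd.out_group)
        )
        S = tuple(
            detection.group_presence(short_flags, g)
            for g in (rnd.in_group, rnd.mid_group, rnd.out_group)
        )
        pattern = detection.ACCEPTED_PATTERNS.get((L, S))
        if pattern is not None:
            return rnd.index, pattern
    return None, None


_SUBPATTERN = {
    ("I", "same_region"): "A",
    ("I", "dispersed"): "B",
    ("I", "near_one"): "C",
    ("II", "dispersed"): "D",
    ("II", "near_one"): "E",
    ("III", "dispersed"): "F",
    ("III", "same_region"): "G",
}


def _expected_type(plan: SimulationPlan, ev: PlantedFusion, sp: str) -> tuple[str, str]:
    n = int(plan.parent_present(ev, "a", sp)) + int(plan.parent_present(ev, "b", sp))
    type_ = {2: "I", 1: "II", 0: "III"}[n]
    return type_, _SUBPATTERN[(type_, ev.placement)]


# ---------------------------------------------------------------------------
# Sequence evolution


def _mutate(seq: str, p: float, rng: np.random.Generator) -> str:
    if p <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    mask = rng.random(arr.size) < p
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return seq
    chars = list(seq)
    shifts = rng.integers(1, len(AA_ALPHABET), size=idx.size)
    for k, shift in zip(idx, shifts):
        chars[k] = AA_ALPHABET[(_AA_INDEX[chars[k]] + int(shift)) % len(AA_ALPHABET)]
    return "".join(chars)


def _percent_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * matches / len(a)


class _SimState:
    """Internal intermediate state shared by the generator stages."""

    def __init__(self, plan: SimulationPlan):
        self.plan = plan
        self.leaf_seqs: dict[str, dict[tuple, str]] = {}
        self.models: dict[str, dict[str, GeneModel]] = {}  # species -> gid -> model
        self.genomes: dict[str, dict[str, str]] = {}  # species -> chrom -> seq
        self.protein_fastas: dict[str, list[tuple[str, str]]] = {}

    def gene_id(self, key: tuple, species: str) -> str:
        if key[0] == "bg":
            return f"{species}_g{key[1]:03d}"
        return f"{species}_{key[1]}"

    def present(self, key: tuple, species: str) -> bool:
        if key[0] == "bg":
            return self.plan.bg_present(key[1], species)
        ev = next(e for e in self.plan.events if e.name == key[1])
        return species in ev.branch


def _evolve_sequences(plan: SimulationPlan, rng: np.random.Generator) -> _SimState:
    state = _SimState(plan)
    lo, hi = plan.protein_length_range
    lengths = rng.integers(lo, hi + 1, size=plan.n_background_genes)
    root: dict[tuple, str] = {}
    for i in range(plan.n_background_genes):
        letters = rng.integers(0, len(AA_ALPHABET), size=int(lengths[i]))
        root[("bg", i)] = "".join(AA_ALPHABET[j] for j in letters)
    events_by_clade: dict[frozenset, list[PlantedFusion]] = {}
    for ev in plan.events:
        events_by_clade.setdefault(ev.branch, []).append(ev)

    def descend(node, seqs: dict[tuple, str]) -> None:
        clade = Phylogeny.leaf_set(node)
        for ev in sorted(events_by_clade.get(clade, []), key=lambda e: e.name):
            seqs[("fus", ev.name)] = seqs[("bg", ev.parent_a)] + seqs[("bg", ev.parent_b)]
        children = node.child_nodes()
        if not children:
            state.leaf_seqs[node.taxon.label] = seqs
            return
        for child in children:
            mutated = {k: _mutate(s, plan.branch_sub_prob, rng) for k, s in sorted(seqs.items())}
            descend(child, mutated)

    descend(plan.phylogeny.tree.seed_node, dict(root))
    return state


# ---------------------------------------------------------------------------
# Annotation / genome layout


def _gene_structure(plan: SimulationPlan, key: tuple) -> tuple[int, str]:
    """(number of CDS exons, strand) for a gene; identical in all species."""
    if key[0] == "fus":
        ev = next(e for e in plan.events if e.name == key[1])
        return (1 if ev.retro else 2), "+"
    i = key[1]
    for ev in plan.events:
        if i == ev.parent_a:
            return (3 if ev.retro else 1), "+"
        if i == ev.parent_b:
            return 1, "+"
    n_exons = 2 if i % 5 == 0 else 1
    strand = "-" if i % 4 == 3 else "+"
    return n_exons, strand


def _exon_splits(
    key: tuple, cds_len: int, n_exons: int, parent_a_len: int | None = None
) -> list[int]:
    """Interior nt offsets where the CDS is cut into exons (5'→3')."""
    if n_exons <= 1:
        return []
    if key[0] == "fus":  # cut inside the parent_a-derived half
        assert parent_a_len is not None
        return [3 * (parent_a_len // 2)]
    step = cds_len // n_exons
    return [step * k for k in range(1, n_exons)]


def _reverse_translate(protein: str) -> str:
    return "".join(CODON[a] for a in protein) + "TAA"


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _species_layout(plan: SimulationPlan, state: _SimState, sp: str) -> list[tuple[tuple, int]]:
    """Ordered (gene key, gap before gene) list along the one chromosome."""
    order: list[tuple] = [
        ("bg", i) for i in range(plan.n_background_genes) if plan.bg_present(i, sp)
    ]
    gaps: dict[tuple, int] = {}
    far, near = plan.intergenic_gap, plan.near_gap
    for ev in plan.events:
        pa = ("bg", ev.parent_a) if plan.parent_present(ev, "a", sp) else None
        pb = ("bg", ev.parent_b) if plan.parent_present(ev, "b", sp) else None
        fus = ("fus", ev.name) if sp in ev.branch else None
        if ev.placement == "same_region":
            if pa and pb:
                order.remove(pb)
                order.insert(order.index(pa) + 1, pb)
                gaps[pb] = near
            if fus:
                anchor = pb or pa
                if anchor:
                    order.insert(order.index(anchor) + 1, fus)
                    gaps[fus] = near
                else:
                    order.append(fus)
        elif ev.placement == "near_one":
            if fus:
                anchor = pa or pb
                if anchor:
                    order.insert(order.index(anchor) + 1, fus)
                    gaps[fus] = near
                else:
                    order.append(fus)
        else:
            if fus:
                order.append(fus)
    return [(key, gaps.get(key, far)) for key in order]


def _build_annotation(
    plan: SimulationPlan,
    state: _SimState,
    sp: str,
    rng: np.random.Generator,
    materialize: bool,
) -> None:
    """Lay the species' genes on one chromosome; optionally build its DNA."""
    layout = _species_layout(plan, state, sp)
    seqs = state.leaf_seqs[sp]
    pos = 0
    chunks: list[str] = []

    def filler(n: int) -> None:
        nonlocal pos
        if materialize and n > 0:
            letters = rng.integers(0, 4, size=n)
            chunks.append("".join("ACGT"[j] for j in letters))
        pos += n

    models: dict[str, GeneModel] = {}
    fasta: list[tuple[str, str]] = []
    pos = 0
    filler(1000)
    for key, gap in layout:
        filler(gap)
        protein = seqs[key]
        gid = state.gene_id(key, sp)
        cds = _reverse_translate(protein)
        n_exons, strand = _gene_structure(plan, key)
        parent_a_len = None
        if key[0] == "fus":
            ev = next(e for e in plan.events if e.name == key[1])
            parent_a_len = len(seqs[("bg", ev.parent_a)])
        splits = _exon_splits(key, len(cds), n_exons, parent_a_len)
        cuts = [0] + splits + [len(cds)]
        exon_seqs = [cds[a:b] for a, b in zip(cuts, cuts[1:])]
        if materialize:
            intron_bodies = [
                "GT"
                + "".join("ACGT"[j] for j in rng.integers(0, 4, size=INTRON_LEN - 4))
                + "AG"
                for _ in range(len(exon_seqs) - 1)
            ]
        else:
            intron_bodies = ["N" * INTRON_LEN] * (len(exon_seqs) - 1)
        transcript_parts: list[tuple[str, str]] = []  # (kind, seq)
        for i, ex in enumerate(exon_seqs):
            transcript_parts.append(("exon", ex))
            if i < len(intron_bodies):
                transcript_parts.append(("intron", intron_bodies[i]))
        transcript = "".join(s for _k, s in transcript_parts)
        gene_start = pos
        gene_end = pos + len(transcript)
        # exon coordinates in transcript orientation, then genomic
        exons_tx: list[tuple[int, int]] = []
        off = 0
        for kind, s in transcript_parts:
            if kind == "exon":
                exons_tx.append((off, off + len(s)))
            off += len(s)
        if strand == "+":
            genomic_exons = [(gene_start + a, gene_start + b) for a, b in exons_tx]
            placed = transcript
        else:
            L = len(transcript)
            genomic_exons = [(gene_start + L - b, gene_start + L - a) for a, b in exons_tx]
            genomic_exons.reverse()
            placed = _revcomp(transcript)
        if materialize:
            chunks.append(placed)
        pos = gene_end
        exons_5p3p = sorted(genomic_exons)
        if strand == "-":
            exons_5p3p = list(reversed(exons_5p3p))
        models[gid] = GeneModel(
            gene_id=gid,
            chrom="chr1",
            strand=strand,
            start=gene_start,
            end=gene_end,
            cds_exons=tuple(exons_5p3p),
            protein_id=f"{gid}.t1",
        )
        fasta.append((gid, protein))
    filler(1000)
    state.models[sp] = models
    state.protein_fastas[sp] = fasta
    if materialize:
        state.genomes[sp] = {"chr1": "".join(chunks)}


def _write_fasta(path: Path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_gff3(path: Path, models: Mapping[str, GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(models, key=lambda g: models[g].start):
            m = models[gid]
            fh.write(
                f"{m.chrom}\tsim\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={gid}\n"
            )
            tid = f"{gid}.t1"
            fh.write(
                f"{m.chrom}\tsim\tmRNA\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={tid};Parent={gid}\n"
            )
            phase = 0
            for s, e in m.cds_exons:  # 5'→3' order keeps phase bookkeeping simple
                fh.write(
                    f"{m.chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t{phase}\t"
                    f"ID={tid}.cds;Parent={tid}\n"
                )
                phase = (3 - ((e - s - phase) % 3)) % 3
    return None


# ---------------------------------------------------------------------------
# Hit synthesis


def _make_hit(
    query_id: str,
    subject_id: str,
    subject_species: str,
    q_span: tuple[int, int],
    s_span: tuple[int, int],
    identity: float,
) -> AlignmentHit:
    length = q_span[1] - q_span[0]
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=round(identity, 2),
        aln_len=length,
        q_start=q_span[0],
        q_end=q_span[1],
        s_start=s_span[0],
        s_end=s_span[1],
        e_value=1e-100,
        bit_score=2.0 * length,
        subject_species=subject_species,
    )


def synthesize_hits(
    plan: SimulationPlan,
    state: _SimState,
    focus: str,
    rng: np.random.Generator | None = None,
) -> list[AlignmentHit]:
    """Tabular alignment hits of one focus species' queries vs every species.

    Hit spans equal the true homologous spans; identity reflects the
    accumulated substitution distance.  With ``noise_hit_rate`` > 0,
    spurious low-identity sub-threshold hits are added at that rate per
    (query, species) pair.
    """
    hits: list[AlignmentHit] = []
    events = {e.name: e for e in plan.events}
    fseqs = state.leaf_seqs[focus]
    for key in sorted(fseqs, key=lambda k: state.gene_id(k, focus)):
        if not state.present(key, focus):
            continue
        qid = state.gene_id(key, focus)
        qseq = fseqs[key]
        for sp in plan.species_order:
            sseqs = state.leaf_seqs[sp]
            if key[0] == "bg":
                i = key[1]
                if plan.bg_present(i, sp):
                    target = sseqs[("bg", i)]
                    hits.append(
                        _make_hit(
                            qid, state.gene_id(("bg", i), sp), sp,
                            (0, len(qseq)), (0, len(target)),
                            _percent_identity(qseq, target),
                        )
                    )
                for ev in plan.events:
                    if sp not in ev.branch:
                        continue
                    la = len(sseqs[("bg", ev.parent_a)])
                    fus_seq = sseqs[("fus", ev.name)]
                    if ev.parent_a == i:
                        s_span = (0, la)
                    elif ev.parent_b == i:
                        s_span = (la, len(fus_seq))
                    else:
                        continue
                    hits.append(
                        _make_hit(
                            qid, state.gene_id(("fus", ev.name), sp), sp,
                            (0, len(qseq)), s_span,
                            _percent_identity(qseq, fus_seq[s_span[0] : s_span[1]]),
                        )
                    )
            else:
                ev = events[key[1]]
                la = len(fseqs[("bg", ev.parent_a)])
                if sp in ev.branch:
                    target = sseqs[("fus", ev.name)]
                    hits.append(
                        _make_hit(
                            qid, state.gene_id(key, sp), sp,
                            (0, len(qseq)), (0, len(target)),
                            _percent_identity(qseq, target),
                        )
                    )
                if plan.parent_present(ev, "a", sp):
                    target = sseqs[("bg", ev.parent_a)]
                    hits.append(
                        _make_hit(
                            qid, state.gene_id(("bg", ev.parent_a), sp), sp,
                            (0, la), (0, len(target)),
                            _percent_identity(qseq[:la], target),
                        )
                    )
                if plan.parent_present(ev, "b", sp):
                    target = sseqs[("bg", ev.parent_b)]
                    hits.append(
                        _make_hit(
                            qid, state.gene_id(("bg", ev.parent_b), sp), sp,
                            (la, len(qseq)), (0, len(target)),
                            _percent_identity(qseq[la:], target),
                        )
                    )
            if rng is not None and plan.noise_hit_rate > 0:
                if rng.random() < plan.noise_hit_rate:
                    present = sorted(
                        state.gene_id(k, sp)
                        for k in state.leaf_seqs[sp]
                        if state.present(k, sp)
                    )
                    subject = present[int(rng.integers(0, len(present)))]
                    span = max(5, int(0.10 * len(qseq)))
                    start = int(rng.integers(0, len(qseq) - span + 1))
                    hits.append(
                        dataclasses.replace(
                            _make_hit(
                                qid, subject, sp,
                                (start, start + span), (0, span), 30.0,
                            ),
                            e_value=1e-8,
                            bit_score=25.0,
                        )
                    )
    return hits


# ---------------------------------------------------------------------------
# Population variants


def _cds_to_genomic(model: GeneModel, k: int) -> int:
    """Genomic 0-based position of CDS nt index *k* (5'→3')."""
    off = 0
    for s, e in model.cds_exons:
        if k < off + (e - s):
            if model.strand == "+":
                return s + (k - off)
            return e - 1 - (k - off)
        off += e - s
    raise IndexError(k)


def _find_stop_site(cds: str) -> tuple[int, str, str] | None:
    """(cds nt index, ref base, alt base) turning a mid-CDS codon into a stop."""
    n_codons = len(cds) // 3
    for ci in range(2, n_codons - 2):
        codon = cds[3 * ci : 3 * ci + 3]
        for stop in STOP_CODONS:
            diff = [k for k in range(3) if codon[k] != stop[k]]
            if len(diff) == 1:
                k = diff[0]
                return 3 * ci + k, codon[k], stop[k]
    return None


def _find_benign_site(cds: str, exclude_ci: int = -1) -> tuple[int, str, str] | None:
    """A substitution that neither creates a stop nor touches one.

    *exclude_ci* skips a codon (the planted disruption site) so the benign
    allele can never cancel the disruptive one in joint carriers.
    """
    n_codons = len(cds) // 3
    for ci in range(2, n_codons - 2):
        if ci == exclude_ci:
            continue
        codon = cds[3 * ci : 3 * ci + 3]
        for k in range(3):
            for alt in "ACGT":
                if alt == codon[k]:
                    continue
                new = codon[:k] + alt + codon[k + 1 :]
                if new not in STOP_CODONS and codon not in STOP_CODONS:
                    return 3 * ci + k, codon[k], alt
    return None


def simulate_population(
    plan: SimulationPlan,
    state: _SimState,
    out_dir: Path,
    truth: Truth,
    rng: np.random.Generator,
) -> dict[str, Path]:
    """Write one VCF per focus species covering its planted fusion genes.

    Each gene gets one potentially ORF-disrupting site (premature stop when
    a codon one substitution from a stop exists, otherwise a 1-bp
    frameshift deletion) carried homozygously by each individual with
    probability ``disruption_prob``, plus one benign segregating
    substitution.  The realized per-gene intact fraction is recorded in the
    truth table.
    """
    paths: dict[str, Path] = {}
    samples = [f"ind{j + 1:04d}" for j in range(plan.n_individuals)]
    for sp in plan.focus_species:
        genome = state.genomes.get(sp)
        if genome is None:
            continue
        chrom_seq = genome["chr1"]
        records: list[tuple[int, str, str, list[str]]] = []
        for ev in sorted(plan.events, key=lambda e: e.name):
            if sp not in ev.branch:
                continue
            gid = state.gene_id(("fus", ev.name), sp)
            model = state.models[sp][gid]
            cds = _reverse_translate(state.leaf_seqs[sp][("fus", ev.name)])
            site = _find_stop_site(cds)
            disrupted = rng.random(plan.n_individuals) < plan.disruption_prob
            disrupt_ci = -1
            if site is not None:
                k, ref, alt = site
                disrupt_ci = k // 3
                pos = _cds_to_genomic(model, k)
                if model.strand == "-":
                    ref, alt = _revcomp(ref), _revcomp(alt)
                gts = ["1/1" if d else "0/0" for d in disrupted]
                records.append((pos, ref, alt, gts))
            else:  # fall back to a 1-bp frameshift deletion
                k = 3 * ((len(cds) // 3) // 2)
                pos = _cds_to_genomic(model, k)
                ref2 = chrom_seq[pos : pos + 2]
                gts = ["1/1" if d else "0/0" for d in disrupted]
                records.append((pos, ref2, ref2[0], gts))
            benign = _find_benign_site(cds, exclude_ci=disrupt_ci)
            if benign is not None:
                k, ref, alt = benign
                pos = _cds_to_genomic(model, k)
                if model.strand == "-":
                    ref, alt = _revcomp(ref), _revcomp(alt)
                het = rng.random(plan.n_individuals) < 0.5
                records.append((pos, ref, alt, ["0/1" if h else "0/0" for h in het]))
            entry = truth.entry(ev.name)
            entry.fixation_freq[sp] = 1.0 - float(np.mean(disrupted))
        path = out_dir / f"{sp}.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID=chr1,length={len(chrom_seq)}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(samples) + "\n")
            for pos, ref, alt, gts in sorted(records):
                fh.write(
                    f"chr1\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                    + "\t".join(gts)
                    + "\n"
                )
        paths[sp] = path
    return paths


# ---------------------------------------------------------------------------
# Expression


def simulate_fpkm(
    plan: SimulationPlan,
    state: _SimState,
    out_dir: Path,
    rng: np.random.Generator,
) -> dict[str, Path]:
    """Write one three-tissue FPKM table per focus species.

    Planted fusions follow their event's expression mode: ``parental_like``
    copies (scaled) the profile of the first parent present in the species,
    ``novel`` draws an independent profile re-sampled until |r| ≤ 0.9
    against every present parent, ``silent`` emits zero.  Regions equal the
    gene spans so the >50% overlap rule assigns them unambiguously.
    """
    n_t = len(plan.tissues)
    paths: dict[str, Path] = {}

    def random_profile() -> np.ndarray:
        while True:
            prof = np.round(rng.lognormal(mean=1.5, sigma=1.0, size=n_t), 3)
            if len(set(prof.tolist())) > 1:
                return prof

    for sp in plan.focus_species:
        models = state.models[sp]
        profiles: dict[str, np.ndarray] = {}
        for i in range(plan.n_background_genes):
            if plan.bg_present(i, sp):
                profiles[state.gene_id(("bg", i), sp)] = random_profile()
        for ev in sorted(plan.events, key=lambda e: e.name):
            if sp not in ev.branch:
                continue
            gid = state.gene_id(("fus", ev.name), sp)
            parent_ids = [
                state.gene_id(("bg", p), sp)
                for p, which in ((ev.parent_a, "a"), (ev.parent_b, "b"))
                if plan.parent_present(ev, which, sp)
            ]
            if ev.expression_mode == "silent":
                profiles[gid] = np.zeros(n_t)
            elif ev.expression_mode == "parental_like" and parent_ids:
                profiles[gid] = np.round(0.5 * profiles[parent_ids[0]], 3)
            else:
                while True:
                    prof = random_profile()
                    ok = True
                    for pid in parent_ids:
                        r = np.corrcoef(prof, profiles[pid])[0, 1]
                        if abs(r) > 0.9:
                            ok = False
                    if ok:
                        profiles[gid] = prof
                        break
        path = out_dir / f"{sp}.fpkm.tsv"
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\ttissue\tspecies\tfpkm\n")
            for gid in sorted(profiles):
                m = models[gid]
                for t_idx, tissue in enumerate(plan.tissues):
                    fh.write(
                        f"{m.chrom}\t{m.start + 1}\t{m.end}\t{tissue}\t{sp}\t"
                        f"{profiles[gid][t_idx]:.3f}\n"
                    )
        paths[sp] = path
    return paths


def _expected_expression(plan: SimulationPlan, ev: PlantedFusion, sp: str) -> str | None:
    if ev.expression_mode == "silent":
        return None  # not expressed: excluded upstream
    has_parent = plan.parent_present(ev, "a", sp) or plan.parent_present(ev, "b", sp)
    if not has_parent:
        return "no-parent-data"
    return "parental-like" if ev.expression_mode == "parental_like" else "novel"


# ---------------------------------------------------------------------------
# TE annotation


def simulate_te(
    plan: SimulationPlan,
    state: _SimState,
    out_dir: Path,
    truth: Truth,
    rng: np.random.Generator,
) -> dict[str, Path]:
    """A small TE annotation per focus species: every second planted fusion
    locus carries an overlapping TE, plus a few intergenic elements."""
    paths: dict[str, Path] = {}
    for sp in plan.focus_species:
        fusion_gids = sorted(
            state.gene_id(("fus", ev.name), sp)
            for ev in plan.events
            if sp in ev.branch
        )
        flagged = fusion_gids[::2]
        lines = []
        for gid in flagged:
            m = state.models[sp][gid]
            mid = (m.start + m.end) // 2
            lines.append((m.chrom, mid, min(m.end, mid + 300)))
        for _ in range(3):  # background elements away from genes
            start = int(rng.integers(0, 900))
            lines.append(("chr1", start, start + 80))
        path = out_dir / f"{sp}.te.gff3"
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom, s, e in sorted(lines):
                fh.write(
                    f"{chrom}\tsim\ttransposable_element\t{s + 1}\t{e}\t.\t+\t.\t"
                    f"ID=te_{s}\n"
                )
        truth.te_counts[sp] = len(flagged)
        truth.te_flagged[sp] = frozenset(flagged)
        paths[sp] = path
    return paths


# ---------------------------------------------------------------------------
# Bundle orchestration


@dataclass
class SimulatedBundle:
    """A complete on-disk input set plus its ground truth."""

    plan: SimulationPlan
    out_dir: Path
    config_path: Path
    config: ControlConfig
    truth: Truth


def simulate_bundle(plan: SimulationPlan, out_dir: str | Path) -> SimulatedBundle:
    """Generate the full input bundle for a plan under *out_dir*.

    Writes per-species protein FASTA and GFF3, per-focus-species hit
    tables, genome FASTA (per ``write_genomes``), population VCFs, FPKM
    tables, TE annotations, a ready-to-run control file and the truth
    table.  Identical plans produce byte-identical output.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = plan.seed
    rng_seq = np.random.default_rng([seed, 1])
    rng_genome = np.random.default_rng([seed, 2])
    rng_pop = np.random.default_rng([seed, 3])
    rng_fpkm = np.random.default_rng([seed, 4])
    rng_noise = np.random.default_rng([seed, 5])

    state = _evolve_sequences(plan, rng_seq)
    materialized = set()
    if plan.write_genomes == "all":
        materialized = set(plan.species_order)
    elif plan.write_genomes == "focus":
        materialized = set(plan.focus_species)
    for sp in plan.species_order:
        _build_annotation(plan, state, sp, rng_genome, materialize=sp in materialized)

    truth = Truth(entries=[])
    for ev in sorted(plan.events, key=lambda e: e.name):
        entry = TruthEntry(
            name=ev.name,
            carriers=ev.branch,
            fusion_ids={sp: state.gene_id(("fus", ev.name), sp) for sp in ev.branch},
            parent_ids={
                sp: tuple(
                    state.gene_id(("bg", p), sp)
                    for p, w in ((ev.parent_a, "a"), (ev.parent_b, "b"))
                    if plan.parent_present(ev, w, sp)
                )
                for sp in plan.species_order
            },
            parent_len_a=len(state.leaf_seqs[plan.species_order[0]][("bg", ev.parent_a)]),
            parent_len_b=len(state.leaf_seqs[plan.species_order[0]][("bg", ev.parent_b)]),
            retro=ev.retro,
            expected_round={},
            expected_pattern={},
            expected_type={},
            expected_subpattern={},
            expected_expression={},
        )
        for focus in plan.focus_species:
            if focus in ev.branch:
                rnd, pattern = _expected_call(plan, ev, focus)
                entry.expected_round[focus] = rnd
                entry.expected_pattern[focus] = pattern
                type_, sub = _expected_type(plan, ev, focus)
                entry.expected_type[focus] = type_
                entry.expected_subpattern[focus] = sub
                entry.expected_expression[focus] = _expected_expression(plan, ev, focus)
        truth.entries.append(entry)

    paths: dict[str, dict[str, str]] = {}
    for sp in plan.species_order:
        pdir = out_dir
        prot = pdir / f"{sp}.proteins.faa"
        _write_fasta(prot, state.protein_fastas[sp])
        gff = pdir / f"{sp}.gff3"
        _write_gff3(gff, state.models[sp])
        paths[sp] = {"proteins": str(prot), "gff": str(gff)}
        if sp in materialized:
            gpath = pdir / f"{sp}.genome.fa"
            _write_fasta(gpath, [("chr1", state.genomes[sp]["chr1"])])
            paths[sp]["genome"] = str(gpath)
    for focus in plan.focus_species:
        hits = synthesize_hits(
            plan, state, focus, rng_noise if plan.noise_hit_rate > 0 else None
        )
        hpath = out_dir / f"{focus}.hits.tsv"
        write_hit_table(hits, hpath)
        paths[focus]["hits"] = str(hpath)

    if plan.events:
        for sp, p in simulate_population(plan, state, out_dir, truth, rng_pop).items():
            paths[sp]["vcf"] = str(p)
        for sp, p in simulate_fpkm(plan, state, out_dir, rng_fpkm).items():
            paths[sp]["fpkm"] = str(p)
        for sp, p in simulate_te(plan, state, out_dir, truth, rng_fpkm).items():
            paths[sp]["te"] = str(p)

    control = {
        "species": list(plan.species_order),
        "focus": list(plan.focus_species),
        "outgroup": list(plan.outgroup_species),
        "tree": plan.newick,
        "divergence_my": 1.0,
        "tissues": list(plan.tissues),
        "params": {"adjacency_kb": plan.adjacency_kb},
        "paths": {sp: {k: str(Path(v).name) for k, v in m.items()} for sp, m in paths.items()},
    }
    config_path = out_dir / "control.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(control, fh, sort_keys=False)
    truth.write_tsv(out_dir / "truth.tsv")

    from .config import load_control

    return SimulatedBundle(
        plan=plan,
        out_dir=out_dir,
        config_path=config_path,
        config=load_control(config_path),
        truth=truth,
    )
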