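"""Origination-pattern typing, retro-fusion flagging and TE intersection.

An expressed fusion gene is typed by how many of its parental genes remain
detectable in the focus genome: both (Type I), one (Type II) or none
(Type III).  Sub-patterns refine the type by genomic position, using an
adjacency threshold (``adjacency_kb``, same chromosome):

* ``A`` — both parents adjacent to each other and to the fusion;
* ``B`` — parents elsewhere in the genome;
* ``C`` — exactly one parent adjacent to the fusion;
* ``D`` — the surviving parent elsewhere;  ``E`` — surviving parent adjacent;
* ``F`` — lost parents' homologs dispersed in other species;
* ``G`` — lost parents' homologs co-located (syntenic) in ≥1 other species.

A *retro-fusion* contribution is recognized structurally: the parent has
introns (≥2 CDS exons) but its homologous span lands inside exactly one CDS
exon of the fusion gene — the hallmark of retroposition from mRNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .errors import CoordinateError
from .genes import GeneLocus, GeneModel, GeneTable, interval_distance
from .homology import CopyCall

__all__ = [
    "ParentLocus",
    "OriginationClass",
    "RetroFlag",
    "locate_parents",
    "classify_type",
    "detect_retrofusion",
    "read_te_annotation",
    "te_overlap",
]

SUBPATTERNS_BY_TYPE = {"I": ("A", "B", "C"), "II": ("D", "E"), "III": ("F", "G")}


@dataclass(frozen=True)
class ParentLocus:
    """A detectable parental gene and the query span it explains."""

    gene_id: str
    locus: GeneLocus
    query_spans: tuple[tuple[int, int], ...]  # residue intervals, 0-based half-open

    @property
    def explained(self) -> int:
        return sum(e - s for s, e in self.query_spans)


@dataclass(frozen=True)
class OriginationClass:
    fusion_id: str
    type: str  # "I" | "II" | "III"
    subpattern: str  # "A".."G"
    parents_in_focus: int
    parents: tuple[ParentLocus, ...]
    notes: str = ""


@dataclass(frozen=True)
class RetroFlag:
    fusion_id: str
    parent_id: str
    parent_exon_count: int
    fusion_span_exon_count: int
    is_retro: bool


def locate_parents(
    fusion_id: str,
    self_call: CopyCall,
    gene_table: GeneTable,
    fusion_locus: GeneLocus | None = None,
) -> list[ParentLocus]:
    """Parental genes detectable in the focus species.

    Parents are the distinct subject genes behind the query's short hits in
    its own species, excluding the fusion gene itself and any gene whose
    locus overlaps it.  Subjects missing from the annotation are warned
    about and treated as undetectable.
    """
    spans_by_gene: dict[str, list[tuple[int, int]]] = {}
    for hit in self_call.short_hits:
        gid = gene_table.gene_for(hit.subject_id)
        if gid is None:
            warnings.warn(
                f"short-hit subject {hit.subject_id!r} absent from the annotation; "
                "parent counted as undetectable",
                stacklevel=2,
            )
            continue
        if gid == fusion_id:
            continue
        locus = gene_table.by_gene[gid].locus
        if fusion_locus is not None and locus.overlaps(fusion_locus):
            continue
        spans_by_gene.setdefault(gid, []).append((hit.q_start, hit.q_end))
    parents = [
        ParentLocus(
            gene_id=gid,
            locus=gene_table.by_gene[gid].locus,
            query_spans=tuple(sorted(spans)),
        )
        for gid, spans in spans_by_gene.items()
    ]
    # widest-explaining parents first, stable on gene id
    parents.sort(key=lambda p: (-p.explained, p.gene_id))
    return parents


def _adjacent(a: GeneLocus, b: GeneLocus, adjacency_kb: float) -> bool:
    return interval_distance(a, b) <= adjacency_kb * 1000.0


def classify_type(
    fusion_id: str,
    fusion_locus: GeneLocus,
    parents: Sequence[ParentLocus],
    other_species_parent_loci: Mapping[str, Sequence[GeneLocus]],
    adjacency_kb: float,
) -> OriginationClass:
    """Assign the origination type and positional sub-pattern.

    *parents* come from :func:`locate_parents`; for Type III the synteny of
    the lost parents is judged from *other_species_parent_loci*, the loci of
    the query's short-hit subjects in each non-focus species.
    """
    n = len(parents)
    if n >= 2:
        pa, pb = parents[0], parents[1]
        near_a = _adjacent(pa.locus, fusion_locus, adjacency_kb)
        near_b = _adjacent(pb.locus, fusion_locus, adjacency_kb)
        if near_a and near_b and _adjacent(pa.locus, pb.locus, adjacency_kb):
            sub, note = "A", "both parents and fusion in the same region"
        elif near_a != near_b:
            sub, note = "C", "fusion adjacent to one parent"
        else:
            sub, note = "B", "fusion located away from both parents"
        return OriginationClass(fusion_id, "I", sub, 2, tuple(parents), note)
    if n == 1:
        parent = parents[0]
        if _adjacent(parent.locus, fusion_locus, adjacency_kb):
            sub, note = "E", "fusion adjacent to the surviving parent"
        else:
            sub, note = "D", "fusion located away from the surviving parent"
        return OriginationClass(fusion_id, "II", sub, 1, tuple(parents), note)
    co_located = False
    for sp in sorted(other_species_parent_loci):
        loci = list(other_species_parent_loci[sp])
        for i in range(len(loci)):
            for j in range(i + 1, len(loci)):
                if _adjacent(loci[i], loci[j], adjacency_kb):
                    co_located = True
    if co_located:
        sub, note = "G", "parental homologs co-located in at least one other species"
    else:
        sub, note = "F", "parental homologs dispersed in other species"
    return OriginationClass(fusion_id, "III", sub, 0, (), note)


def detect_retrofusion(
    fusion_model: GeneModel,
    parent_model: GeneModel,
    fusion_query_span: tuple[int, int],
) -> RetroFlag:
    """Flag an intron-loss (retroposed) parental contribution.

    *fusion_query_span* is the residue interval of the fusion protein
    homologous to the parent (0-based half-open).  The span is mapped onto
    the fusion's CDS (3 nt per residue, cumulative over 5'→3' exons); the
    contribution is retro when the parent has ≥2 CDS exons but the mapped
    span stays inside exactly one fusion exon.
    """
    res_start, res_end = fusion_query_span
    if res_start < 0 or res_end <= res_start:
        raise CoordinateError(f"invalid protein span {fusion_query_span}")
    nt_start, nt_end = res_start * 3, res_end * 3
    if nt_end > fusion_model.cds_length:
        raise CoordinateError(
            f"span {fusion_query_span} maps beyond the CDS of {fusion_model.gene_id} "
            f"({fusion_model.cds_length} nt)"
        )
    touched = 0
    offset = 0
    for s, e in fusion_model.cds_exons:
        exon_len = e - s
        if nt_start < offset + exon_len and offset < nt_end:
            touched += 1
        offset += exon_len
    return RetroFlag(
        fusion_id=fusion_model.gene_id,
        parent_id=parent_model.gene_id,
        parent_exon_count=parent_model.n_exons,
        fusion_span_exon_count=touched,
        is_retro=parent_model.n_exons >= 2 and touched == 1,
    )


def read_te_annotation(path: str | Path) -> dict[str, IntervalTree]:
    """Read TE features from GFF3 (1-based inclusive) or BED (0-based
    half-open, chosen by the ``.bed`` extension) into per-chromosome trees."""
    path = Path(path)
    trees: dict[str, IntervalTree] = {}
    is_bed = path.suffix.lower() == ".bed"
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if is_bed:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            else:
                chrom, start, end = fields[0], int(fields[3]) - 1, int(fields[4])
            if end > start:
                trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def te_overlap(
    loci: Iterable[GeneLocus], te_trees: Mapping[str, IntervalTree]
) -> tuple[dict[str, bool], int]:
    """Per-locus TE intersection flags (≥1 bp) and the flagged-locus count."""
    flags: dict[str, bool] = {}
    known_chroms = set(te_trees)
    for locus in loci:
        if locus.chrom not in known_chroms:
            if te_trees:
                warnings.warn(
                    f"chromosome {locus.chrom!r} absent from the TE annotation",
                    stacklevel=2,
                )
            flags[locus.gene_id] = False
            continue
        flags[locus.gene_id] = bool(te_trees[locus.chrom].overlap(locus.start, locus.end))
    return flags, sum(flags.values())
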