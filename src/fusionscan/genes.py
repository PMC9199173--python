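"""Gene models read from GFF3: loci, CDS exon structure, isoform→locus map.

Genomic coordinates are 1-based inclusive in GFF3 and 0-based half-open in
memory.  CDS exons are stored in 5'→3' transcription order (reversed genomic
order on the minus strand).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import gffutils

from .errors import CoordinateError

__all__ = ["GeneLocus", "GeneModel", "GeneTable", "read_gene_models", "interval_distance"]


@dataclass(frozen=True)
class GeneLocus:
    """A genomic interval with identity; 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GeneLocus") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def interval_distance(a: GeneLocus, b: GeneLocus) -> float:
    """Gap in bp between two loci; 0 when overlapping, inf across chromosomes."""
    if a.chrom != b.chrom:
        return float("inf")
    return float(max(0, max(a.start, b.start) - min(a.end, b.end)))


@dataclass(frozen=True)
class GeneModel:
    """One protein-coding gene model (a single representative isoform)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds_exons: tuple[tuple[int, int], ...]  # 5'→3' order, 0-based half-open
    protein_id: str | None = None

    def __post_init__(self) -> None:
        genomic = sorted(self.cds_exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise CoordinateError(
                    f"gene {self.gene_id}: CDS exons overlap ({s1},{e1}) ({s2},{e2})"
                )
        if self.cds_length % 3 != 0:
            warnings.warn(
                f"gene {self.gene_id}: CDS length {self.cds_length} "
                "is not a multiple of 3",
                stacklevel=2,
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_exons)

    @property
    def n_exons(self) -> int:
        return len(self.cds_exons)

    @property
    def locus(self) -> GeneLocus:
        return GeneLocus(self.gene_id, self.chrom, self.start, self.end, self.strand)

    def genomic_exons(self) -> tuple[tuple[int, int], ...]:
        """CDS exons in ascending genomic order regardless of strand."""
        return tuple(sorted(self.cds_exons))


class GeneTable:
    """Gene models of one annotation, addressable by gene or protein id."""

    def __init__(self, models: Iterable[GeneModel]):
        self.by_gene: dict[str, GeneModel] = {}
        self.gene_of_protein: dict[str, str] = {}
        for m in models:
            self.by_gene[m.gene_id] = m
            if m.protein_id is not None:
                self.gene_of_protein[m.protein_id] = m.gene_id
            self.gene_of_protein.setdefault(m.gene_id, m.gene_id)

    def gene_for(self, any_id: str) -> str | None:
        """Resolve a protein/mRNA/gene id to its gene id, None if unknown."""
        return self.gene_of_protein.get(any_id)

    def model_for(self, any_id: str) -> GeneModel | None:
        gid = self.gene_for(any_id)
        return self.by_gene.get(gid) if gid is not None else None

    def loci(self) -> dict[str, GeneLocus]:
        return {gid: m.locus for gid, m in self.by_gene.items()}

    def __len__(self) -> int:
        return len(self.by_gene)

    def __iter__(self):
        return iter(self.by_gene.values())


def read_gene_models(gff_path: str | Path) -> GeneTable:
    """Load gene/mRNA/CDS features from GFF3 into a :class:`GeneTable`.

    One model is kept per gene (its first mRNA in file order); the mRNA id
    doubles as the protein id for isoform→locus resolution.
    """
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if mrnas:
            mrna = mrnas[0]
            cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
            protein_id = mrna.id
        else:  # gene with CDS directly attached
            cds = list(db.children(gene, featuretype="CDS", order_by="start"))
            protein_id = gene.id
        exons = [(c.start - 1, c.end) for c in cds]
        exons.sort()
        if gene.strand == "-":
            exons.reverse()
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start - 1,
                end=gene.end,
                cds_exons=tuple(exons),
                protein_id=protein_id,
            )
        )
    return GeneTable(models)
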