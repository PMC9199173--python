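"""Population ORF integrity, fixation frequency and origination-rate estimators.

A fusion gene is *fixed* in an individual when its coding sequence, after
substituting that individual's alternate alleles, still encodes an intact
open reading frame: the length stays a multiple of 3 and no premature stop
codon appears.  The fixation frequency of a gene in a species is the
fraction of individuals with an intact fused ORF; the gene is fixed in the
species when that fraction reaches ``fixation_threshold`` (default 0.80).

Rate estimators are simple arithmetic on counts: the birth rate divides the
species-specific fusion count by species number and divergence time; the
age of the oldest gene follows from synonymous divergence as Ks/(2μ).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from cyvcf2 import VCF

from .config import Parameters
from .errors import CoordinateError, FusionscanError
from .genes import GeneModel

__all__ = [
    "Variant",
    "FixationResult",
    "extract_cds",
    "apply_variants",
    "orf_intact",
    "fixation_frequency",
    "read_population_vcf",
    "birth_rate",
    "weighted_rate",
    "ks_to_age",
    "rate_from_age",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class Variant:
    """A normalized biallelic variant; ``pos`` is 1-based like VCF."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def start(self) -> int:  # 0-based
        return self.pos - 1

    @property
    def end(self) -> int:  # half-open
        return self.pos - 1 + len(self.ref)


def extract_cds(model: GeneModel, chrom_seq: str) -> str:
    """Concatenate the CDS exons 5'→3' (reverse-complemented on minus)."""
    plus = _plus_strand_cds(model, chrom_seq)
    if model.strand == "-":
        return str(Seq(plus).reverse_complement())
    return plus


def _plus_strand_cds(model: GeneModel, chrom_seq: str) -> str:
    parts = []
    for s, e in model.genomic_exons():
        if s < 0 or e > len(chrom_seq):
            raise CoordinateError(
                f"gene {model.gene_id}: exon ({s},{e}) outside chromosome "
                f"{model.chrom} of length {len(chrom_seq)}"
            )
        parts.append(chrom_seq[s:e])
    return "".join(parts).upper()


def apply_variants(
    model: GeneModel, chrom_seq: str, variants: Sequence[Variant]
) -> str:
    """CDS carrying the given alternate alleles of one individual.

    Only variants intersecting the CDS exons are applied; substitutions and
    indels are both supported as long as the reference allele lies inside a
    single exon.  The reference allele is checked against the chromosome and
    a mismatch is an error naming the site.
    """
    exons = model.genomic_exons()
    offsets = []
    off = 0
    for s, e in exons:
        offsets.append(off)
        off += e - s
    plus = _plus_strand_cds(model, chrom_seq)
    edits: list[tuple[int, str, str]] = []  # (spliced position, ref, alt)
    for v in variants:
        if v.chrom != model.chrom:
            continue
        hit_exon = None
        for (s, e), exon_off in zip(exons, offsets):
            if v.start < e and s < v.end:
                if not (s <= v.start and v.end <= e):
                    raise FusionscanError(
                        f"variant {v.chrom}:{v.pos} {v.ref}>{v.alt} crosses an exon "
                        f"boundary of {model.gene_id}; split it upstream"
                    )
                hit_exon = (s, exon_off)
                break
        if hit_exon is None:
            continue  # variant outside the CDS
        observed = chrom_seq[v.start : v.end].upper()
        if observed != v.ref.upper():
            raise FusionscanError(
                f"reference mismatch at {v.chrom}:{v.pos}: VCF says {v.ref!r}, "
                f"sequence has {observed!r}"
            )
        s, exon_off = hit_exon
        edits.append((exon_off + (v.start - s), v.ref.upper(), v.alt.upper()))
    edits.sort(key=lambda t: t[0], reverse=True)
    seq = plus
    for pos, ref, alt in edits:
        seq = seq[:pos] + alt + seq[pos + len(ref) :]
    if model.strand == "-":
        return str(Seq(seq).reverse_complement())
    return seq


def orf_intact(cds: str) -> bool:
    """True iff length ≡ 0 mod 3 and no stop before the final codon.

    Codons containing ambiguous bases (N) are never called as stops.
    """
    cds = cds.upper()
    if len(cds) < 3 or len(cds) % 3 != 0:
        return False
    for i in range(0, len(cds) - 3, 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            continue
        if codon in STOP_CODONS:
            return False
    return True


@dataclass(frozen=True)
class FixationResult:
    gene_id: str
    species: str
    n_individuals: int
    n_fixed: int
    frequency: float
    fixed_in_species: bool


def fixation_frequency(
    model: GeneModel,
    chrom_seq: str,
    variants: Sequence[Variant],
    genotypes: np.ndarray,
    species: str,
    params: Parameters,
    hom_only: bool = False,
) -> FixationResult:
    """Per-gene fixation frequency over a population.

    *genotypes* is an (n_variants, n_individuals) array of alt-allele counts
    with -1 for missing calls.  An individual carries a variant when any alt
    allele is present (``hom_only`` restricts to homozygotes).  Individuals
    with a missing call at any site of the gene are excluded from the
    denominator.
    """
    genotypes = np.asarray(genotypes)
    if genotypes.ndim != 2 or genotypes.shape[0] != len(variants):
        raise FusionscanError("genotype matrix shape does not match the variant list")
    n_ind = genotypes.shape[1]
    if n_ind == 0:
        raise FusionscanError(f"gene {model.gene_id}: zero individuals")
    threshold = 2 if hom_only else 1
    n_fixed = 0
    n_used = 0
    for j in range(n_ind):
        column = genotypes[:, j]
        if (column < 0).any():
            continue
        n_used += 1
        carried = [v for v, g in zip(variants, column) if g >= threshold]
        if orf_intact(apply_variants(model, chrom_seq, carried)):
            n_fixed += 1
    if n_used == 0:
        raise FusionscanError(
            f"gene {model.gene_id}: no individuals with complete genotypes"
        )
    freq = n_fixed / n_used
    return FixationResult(
        gene_id=model.gene_id,
        species=species,
        n_individuals=n_used,
        n_fixed=n_fixed,
        frequency=freq,
        fixed_in_species=freq >= params.fixation_threshold,
    )


def read_population_vcf(
    path: str | Path,
) -> tuple[list[str], list[Variant], np.ndarray]:
    """Read a VCF into (samples, variants, alt-count matrix).

    The matrix holds 0/1/2 alternate-allele counts and -1 for missing
    genotypes.  Multi-allelic records are rejected with a message asking
    for upstream splitting.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FusionscanError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}; "
                "split multi-allelic sites upstream"
            )
        variants.append(Variant(rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        # gt_types: 0 hom-ref, 1 het, 2 missing, 3 hom-alt
        counts = np.array(
            [{0: 0, 1: 1, 2: -1, 3: 2}[int(t)] for t in rec.gt_types], dtype=int
        )
        rows.append(counts)
    matrix = (
        np.vstack(rows) if rows else np.zeros((0, len(samples)), dtype=int)
    )
    return samples, variants, matrix


# ---------------------------------------------------------------------------
# Rate estimators


def birth_rate(
    n_species_specific: int, n_species: int, divergence_my: float
) -> float:
    """Fusion genes per million years per species."""
    if n_species <= 0:
        raise FusionscanError("n_species must be positive")
    if divergence_my <= 0:
        raise FusionscanError("divergence_my must be positive")
    return n_species_specific / n_species / divergence_my


def weighted_rate(
    base_count: float, shared_count: float, weight_num: float, weight_den: float
) -> float:
    """base + shared × weight; used to down-weight shared events."""
    if weight_den <= 0:
        raise FusionscanError("weight denominator must be positive")
    return base_count + shared_count * weight_num / weight_den


def ks_to_age(ks: float, mu: float) -> float:
    """Age in million years from synonymous divergence: Ks / (2 μ) years."""
    if mu <= 0:
        raise FusionscanError("mu must be positive")
    return ks / (2.0 * mu) / 1e6


def rate_from_age(n_genes: float, age_my: float) -> float:
    """Genes per million years given the age of the oldest gene."""
    if age_my <= 0:
        raise FusionscanError("age_my must be positive")
    return n_genes / age_my
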