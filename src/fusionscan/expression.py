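"""FPKM assignment, fusion-vs-parent correlation and expression classes.

Expression is measured as FPKM over three tissues (root, leaf, panicle by
default).  A measurement region is assigned to a gene when the intersection
covers strictly more than ``fpkm_overlap`` (default 50%) of the region; the
maximum over assigned records represents a gene+tissue, and the maximum over
tissues represents the gene.  A fusion gene's tissue profile is correlated
(Pearson) against each parental profile; the fusion is *parental-like* when
at least one parent correlates with p < 0.05, *novel* when parents have data
but none correlates, and *no-parent-data* otherwise.

With only three tissues the Pearson test has a single degree of freedom, so
"strong" effectively requires |r| ≳ 0.997; profiles pooled over species can
be supplied to gain power.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .genes import GeneLocus

__all__ = [
    "ExpressionProfile",
    "CorrelationResult",
    "read_fpkm_table",
    "assign_fpkm",
    "representative_short_copy",
    "pearson_profile",
    "classify_pattern",
    "tissue_contingency",
    "log_transform",
]

DEFAULT_TISSUES = ("root", "leaf", "panicle")

FPKM_COLUMNS = ["chrom", "start", "end", "tissue", "species", "fpkm"]


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-tissue FPKM of one gene in one species."""

    gene_id: str
    species: str
    fpkm: tuple[float, ...]
    tissues: tuple[str, ...] = DEFAULT_TISSUES

    @property
    def expressed(self) -> bool:
        return any(v > 0 for v in self.fpkm)

    @property
    def representative_level(self) -> float:
        """The maximum FPKM over tissues."""
        return max(self.fpkm)


@dataclass(frozen=True)
class CorrelationResult:
    fusion_id: str
    parent_id: str
    r: float | None
    p: float | None
    strength: str  # "strong" | "weak" | "none" | "undefined"


def read_fpkm_table(path: str | Path) -> pd.DataFrame:
    """Read the FPKM TSV (chrom, start, end, tissue, species, fpkm);
    coordinates 1-based inclusive."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FPKM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"FPKM table missing columns: {missing}")
    return df


def assign_fpkm(
    records: pd.DataFrame,
    loci: Mapping[str, GeneLocus],
    min_overlap: float = 0.50,
    tissues: Sequence[str] = DEFAULT_TISSUES,
) -> dict[tuple[str, str], ExpressionProfile]:
    """Assign FPKM records to gene loci, keyed by (gene, species).

    A record counts for a gene when the intersection covers strictly more
    than *min_overlap* of the record's length; several assigned records for
    one gene+tissue are reduced by maximum.  Genes with no record in a
    species present in the table get an all-zero profile.
    """
    tissues = tuple(tissues)
    species_seen = sorted(set(records["species"])) if len(records) else []
    values: dict[tuple[str, str], dict[str, float]] = {
        (gid, sp): {} for gid in loci for sp in species_seen
    }
    for row in records.itertuples(index=False):
        start0, end = int(row.start) - 1, int(row.end)
        length = end - start0
        if length <= 0:
            continue
        for gid, locus in loci.items():
            if locus.chrom != row.chrom:
                continue
            inter = min(end, locus.end) - max(start0, locus.start)
            if inter <= 0 or inter / length <= min_overlap:
                continue
            per_tissue = values[(gid, row.species)]
            per_tissue[row.tissue] = max(per_tissue.get(row.tissue, 0.0), float(row.fpkm))
    return {
        (gid, sp): ExpressionProfile(
            gene_id=gid,
            species=sp,
            fpkm=tuple(per_tissue.get(t, 0.0) for t in tissues),
            tissues=tissues,
        )
        for (gid, sp), per_tissue in values.items()
    }


def representative_short_copy(
    profiles: Sequence[ExpressionProfile],
) -> ExpressionProfile | None:
    """Per-tissue maximum over a gene's short-copy profiles; None without data."""
    if not profiles:
        return None
    tissues = profiles[0].tissues
    fpkm = tuple(max(p.fpkm[i] for p in profiles) for i in range(len(tissues)))
    return ExpressionProfile(
        gene_id="+".join(sorted({p.gene_id for p in profiles})),
        species=profiles[0].species,
        fpkm=fpkm,
        tissues=tissues,
    )


def pearson_profile(
    fusion_id: str,
    parent_id: str,
    fusion_vec: Sequence[float],
    parent_vec: Sequence[float],
) -> CorrelationResult:
    """Pearson correlation of two tissue profiles with a two-sided t test.

    Zero variance in either vector makes the correlation undefined; such
    pairs are excluded from pattern classification rather than failing.
    """
    if len(fusion_vec) != len(parent_vec) or len(fusion_vec) < 3:
        raise ValueError("profiles must have equal length >= 3")
    if _variance(fusion_vec) == 0 or _variance(parent_vec) == 0:
        return CorrelationResult(fusion_id, parent_id, None, None, "undefined")
    r, p = stats.pearsonr(fusion_vec, parent_vec)
    if p < 0.05:
        strength = "strong"
    elif p < 0.1:
        strength = "weak"
    else:
        strength = "none"
    return CorrelationResult(fusion_id, parent_id, float(r), float(p), strength)


def _variance(v: Sequence[float]) -> float:
    mean = sum(v) / len(v)
    return sum((x - mean) ** 2 for x in v)


def classify_pattern(
    fusion_profile: ExpressionProfile,
    parent_results: Sequence[CorrelationResult],
) -> str:
    """Classify an expressed fusion gene's tissue pattern.

    ``parental-like`` when ≥1 parent correlates strongly, ``no-parent-data``
    when no parent has a usable profile, ``novel`` otherwise.
    """
    if not fusion_profile.expressed:
        raise ValueError(
            f"{fusion_profile.gene_id}: unexpressed genes are excluded upstream"
        )
    usable = [res for res in parent_results if res.strength != "undefined"]
    if not parent_results:
        return "no-parent-data"
    if any(res.strength == "strong" for res in usable):
        return "parental-like"
    if not usable:
        return "no-parent-data"
    return "novel"


def tissue_contingency(
    expressed_counts: Mapping[str, int], n_total: int
) -> dict[tuple[str, str], float]:
    """Pairwise two-sided Fisher exact tests on expressed-gene counts.

    For tissues x and y the 2×2 table is [[k_x, n−k_x], [k_y, n−k_y]].
    """
    for tissue, k in expressed_counts.items():
        if not 0 <= k <= n_total:
            raise ValueError(f"count for {tissue!r} outside [0, {n_total}]")
    out: dict[tuple[str, str], float] = {}
    for x, y in itertools.combinations(sorted(expressed_counts), 2):
        kx, ky = expressed_counts[x], expressed_counts[y]
        table = [[kx, n_total - kx], [ky, n_total - ky]]
        out[(x, y)] = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return out


def log_transform(fpkm: float) -> float:
    """Zero-safe natural-log transform ln(FPKM + 1) used for heat maps."""
    return math.log(fpkm + 1.0)
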