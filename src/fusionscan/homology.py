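"""Pairwise protein alignment hits and long/short homologous copy assortment.

The comparative evidence for a fusion gene is read from standard 12-column
tabular protein alignment output (qseqid sseqid pident length mismatch
gapopen qstart qend sstart send evalue bitscore).  For each query protein and
each subject species the hits are assorted into:

* **long homologous copies** — hits spanning more than ``long_cov`` (default
  80%) of the query: the species carries the full, fused gene;
* **short homologous copies** — of the remaining hits, the longest mutually
  non-overlapping query spans, each covering more than ``short_min_cov``
  (default 20%) of the query: the species carries a separate parental gene.

A species "has short copies" when at least ``min_short_copies`` short copies
remain (distinct subject genes by default) and together they span more than
``short_total_cov`` (default 80%) of the query.

Query coordinates are 1-based inclusive in files and 0-based half-open in
memory; conversion happens only at the parser/writer boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from Bio import SeqIO

from .config import Parameters
from .errors import CoordinateError, HitTableError

__all__ = [
    "AlignmentHit",
    "CopyCall",
    "read_hit_table",
    "write_hit_table",
    "assort_hits",
    "copy_status_matrix",
    "read_protein_lengths",
    "write_copy_status",
]

N_COLUMNS = 12


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment hit; query/subject coordinates 0-based half-open."""

    query_id: str
    subject_id: str
    percent_identity: float
    aln_len: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    subject_species: str | None = None

    @property
    def span(self) -> int:
        """Number of query residues covered."""
        return self.q_end - self.q_start

    def coverage(self, query_len: int) -> float:
        return self.span / query_len

    def overlaps(self, other: "AlignmentHit") -> bool:
        """True when the two hits share at least one query residue."""
        return self.q_start < other.q_end and other.q_start < self.q_end


@dataclass(frozen=True)
class CopyCall:
    """Long/short homologous copy status of one query in one subject species."""

    query_id: str
    species: str
    has_long: bool
    long_hits: tuple[AlignmentHit, ...]
    short_hits: tuple[AlignmentHit, ...]
    short_union_cov: float
    has_short: bool

    @property
    def n_short_subjects(self) -> int:
        return len({h.subject_id for h in self.short_hits})


def read_hit_table(
    path: str | Path,
    species_of: Mapping[str, str] | Callable[[str], str] | None = None,
) -> list[AlignmentHit]:
    """Parse a 12-column tabular alignment file.

    *species_of* resolves each subject id to its species; omitting it leaves
    ``subject_species`` unset.  Reversed query or subject coordinates are
    normalized by swapping.
    """
    resolve: Callable[[str], str] | None
    if species_of is None:
        resolve = None
    elif callable(species_of):
        resolve = species_of
    else:
        mapping = species_of

        def resolve(sid: str) -> str:
            try:
                return mapping[sid]
            except KeyError:
                raise HitTableError(f"unknown subject id {sid!r}: no species mapping")

    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != N_COLUMNS:
                raise HitTableError(
                    f"{path}:{lineno}: expected {N_COLUMNS} tab-separated columns, "
                    f"found {len(fields)}"
                )
            try:
                qs, qe = int(fields[6]), int(fields[7])
                ss, se = int(fields[8]), int(fields[9])
                hit = AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    aln_len=int(fields[3]),
                    q_start=min(qs, qe) - 1,
                    q_end=max(qs, qe),
                    s_start=min(ss, se) - 1,
                    s_end=max(ss, se),
                    e_value=float(fields[10]),
                    bit_score=float(fields[11]),
                    subject_species=resolve(fields[1]) if resolve else None,
                )
            except ValueError as exc:
                raise HitTableError(f"{path}:{lineno}: malformed field: {exc}") from exc
            if hit.aln_len < 1:
                raise HitTableError(f"{path}:{lineno}: alignment length must be >= 1")
            hits.append(hit)
    return hits


def write_hit_table(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits back to the 12-column format (1-based inclusive)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        str(h.aln_len),
                        str(h.aln_len - round(h.aln_len * h.percent_identity / 100.0)),
                        "0",
                        str(h.q_start + 1),
                        str(h.q_end),
                        str(h.s_start + 1),
                        str(h.s_end),
                        f"{h.e_value:.2e}",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


def _short_count(short_hits: Sequence[AlignmentHit], params: Parameters) -> int:
    if params.distinct_subjects:
        return len({h.subject_id for h in short_hits})
    return len(short_hits)


def assort_hits(
    query_id: str,
    species: str,
    query_len: int,
    hits: Iterable[AlignmentHit],
    params: Parameters,
    self_id: str | None = None,
) -> CopyCall:
    """Assort one query's hits against one subject species into a CopyCall.

    Hits covering more than ``long_cov`` of the query are long copies.  The
    remaining hits are sorted by query span (descending; ties broken by bit
    score descending, then subject id, then coordinates, making the result
    independent of input order) and kept greedily when they do not overlap
    any already-kept hit; kept hits covering more than ``short_min_cov``
    are the short copies.  The query's hit to itself (*self_id*) is never a
    short-copy candidate — it is the trivial long copy.
    """
    if query_len <= 0:
        raise CoordinateError(f"query {query_id!r} has non-positive length")
    admitted = []
    for h in hits:
        if h.q_end > query_len:
            raise CoordinateError(
                f"hit {h.query_id}->{h.subject_id} ends at {h.q_end} "
                f"beyond query length {query_len}"
            )
        if h.e_value <= params.evalue_max:
            admitted.append(h)

    long_hits = tuple(h for h in admitted if h.coverage(query_len) > params.long_cov)
    pool = [
        h
        for h in admitted
        if h.coverage(query_len) <= params.long_cov and h.subject_id != self_id
    ]
    pool.sort(
        key=lambda h: (-h.span, -h.bit_score, h.subject_id, h.q_start, h.q_end)
    )
    kept: list[AlignmentHit] = []
    for h in pool:
        if not any(h.overlaps(k) for k in kept):
            kept.append(h)
    short_hits = tuple(
        h for h in kept if h.coverage(query_len) > params.short_min_cov
    )
    union_cov = sum(h.span for h in short_hits) / query_len
    has_short = (
        _short_count(short_hits, params) >= params.min_short_copies
        and union_cov > params.short_total_cov
    )
    return CopyCall(
        query_id=query_id,
        species=species,
        has_long=bool(long_hits),
        long_hits=long_hits,
        short_hits=tuple(sorted(short_hits, key=lambda h: h.q_start)),
        short_union_cov=union_cov,
        has_short=has_short,
    )


def copy_status_matrix(
    query_lengths: Mapping[str, int],
    hits: Iterable[AlignmentHit],
    species: Sequence[str],
    params: Parameters,
) -> dict[tuple[str, str], CopyCall]:
    """One CopyCall per (query, species) pair, over every listed species.

    Hits must carry ``subject_species``.  Species without hits for a query
    yield an all-absent call.  The self hit of each query (same id) is
    handled per :func:`assort_hits`.
    """
    by_pair: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        if h.subject_species is None:
            raise HitTableError(
                f"hit {h.query_id}->{h.subject_id} has no subject species; "
                "pass a species mapping to read_hit_table"
            )
        by_pair.setdefault((h.query_id, h.subject_species), []).append(h)
        if h.query_id not in query_lengths:
            raise CoordinateError(
                f"query {h.query_id!r} missing from the protein FASTA lengths"
            )
    matrix: dict[tuple[str, str], CopyCall] = {}
    for query in query_lengths:
        for sp in species:
            matrix[(query, sp)] = assort_hits(
                query,
                sp,
                query_lengths[query],
                by_pair.get((query, sp), ()),
                params,
                self_id=query,
            )
    return matrix


def read_protein_lengths(path: str | Path) -> dict[str, int]:
    """Sequence lengths keyed by record id from a protein FASTA."""
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_copy_status(
    matrix: Mapping[tuple[str, str], CopyCall], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("query\tspecies\thas_long\tn_short\tshort_union_cov\n")
        for (query, sp) in sorted(matrix):
            call = matrix[(query, sp)]
            fh.write(
                f"{query}\t{sp}\t{int(call.has_long)}\t{len(call.short_hits)}"
                f"\t{call.short_union_cov:.4f}\n"
            )
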