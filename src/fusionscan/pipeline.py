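"""Stage orchestration: groups → detect → collapse → classify → fixation →
expression → report, with a run manifest recording inputs and outputs.

Each stage writes diff-friendly TSV files (header line, ``#`` metadata
allowed) into the output directory.  Stages communicate through an
in-process context; a stage whose prerequisites were not produced in the
same run fails with an error naming the stage to run first.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from . import __version__
from .classification import (
    classify_type,
    detect_retrofusion,
    locate_parents,
    read_te_annotation,
    te_overlap,
)
from .config import ControlConfig
from .detection import (
    FusionSet,
    collapse_orthologs,
    detect_focus_species,
    shared_specific_table,
    topology_consistent,
)
from .errors import StageError
from .expression import (
    assign_fpkm,
    classify_pattern,
    pearson_profile,
    read_fpkm_table,
    representative_short_copy,
)
from .genes import read_gene_models
from .homology import (
    copy_status_matrix,
    read_hit_table,
    read_protein_lengths,
    write_copy_status,
)
from .popfix import birth_rate, fixation_frequency, read_population_vcf

STAGE_ORDER = (
    "groups",
    "detect",
    "collapse",
    "classify",
    "fixation",
    "expression",
    "report",
)


@dataclass
class RunManifest:
    config_hash: str
    stages: list[str]
    inputs: dict[str, str]
    outputs: dict[str, str] = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class PipelineContext:
    """In-memory artifacts shared between stages of one run."""

    config: ControlConfig
    out_dir: Path
    matrices: dict = field(default_factory=dict)  # focus -> copy matrix
    hits: dict = field(default_factory=dict)  # focus -> hit list
    calls: dict = field(default_factory=dict)  # focus -> [FusionCall]
    gene_tables: dict = field(default_factory=dict)  # species -> GeneTable
    fusion_set: FusionSet | None = None
    parents: dict = field(default_factory=dict)  # (focus, query) -> [ParentLocus]
    classes: dict = field(default_factory=dict)  # (focus, query) -> OriginationClass
    retro: dict = field(default_factory=dict)  # (focus, query) -> [RetroFlag]
    fixation: dict = field(default_factory=dict)  # (focus, gene) -> FixationResult
    expression_classes: dict = field(default_factory=dict)

    def gene_table(self, species: str):
        if species not in self.gene_tables:
            self.gene_tables[species] = read_gene_models(
                self.config.path(species, "gff")
            )
        return self.gene_tables[species]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(ctx: PipelineContext, attr: str, needed_by: str, producer: str) -> None:
    value = getattr(ctx, attr)
    if not value:
        raise StageError(
            f"stage {needed_by!r} needs results of stage {producer!r}; "
            f"run {producer!r} first"
        )


# ---------------------------------------------------------------------------
# Stages


def stage_groups(ctx: PipelineContext) -> list[Path]:
    path = ctx.out_dir / "groups.tsv"
    with open(path, "w") as fh:
        fh.write("focus\tround\tin_group\tmid_group\tout_group\n")
        for focus in ctx.config.focus_species:
            for rnd in ctx.config.rounds_for(focus):
                fh.write(
                    f"{focus}\t{rnd.index}\t{','.join(sorted(rnd.in_group))}\t"
                    f"{','.join(sorted(rnd.mid_group))}\t"
                    f"{','.join(sorted(rnd.out_group))}\n"
                )
    return [path]


def _species_map(config: ControlConfig) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for sp in config.species:
        for rec in SeqIO.parse(str(config.path(sp, "proteins")), "fasta"):
            mapping[rec.id] = sp
    return mapping


def stage_detect(ctx: PipelineContext) -> list[Path]:
    config = ctx.config
    missing = [
        str(config.path(f, "hits"))
        for f in config.focus_species
        if not config.path(f, "hits").exists()
    ]
    if missing:
        raise StageError(f"stage 'detect' is missing hit tables: {missing}")
    species_map = _species_map(config)
    for focus in config.focus_species:
        lengths = read_protein_lengths(config.path(focus, "proteins"))
        hits = read_hit_table(config.path(focus, "hits"), species_map)
        matrix = copy_status_matrix(lengths, hits, config.species, config.params)
        table = ctx.gene_table(focus)
        calls = detect_focus_species(
            focus,
            matrix,
            config.rounds_for(focus),
            config.params,
            loci=table.loci(),
            gene_of=table.gene_of_protein,
        )
        ctx.matrices[focus] = matrix
        ctx.hits[focus] = hits
        ctx.calls[focus] = calls
    out = []
    status_path = ctx.out_dir / "copy_status.tsv"
    merged = {}
    for matrix in ctx.matrices.values():
        merged.update(matrix)
    write_copy_status(merged, status_path)
    out.append(status_path)
    calls_path = ctx.out_dir / "fusion_calls.tsv"
    with open(calls_path, "w") as fh:
        fh.write("query\tspecies\tpattern\tround\tchrom\tstart\tend\tstrand\tgene\n")
        for focus in config.focus_species:
            for c in ctx.calls[focus]:
                locus = c.locus
                loc = (
                    f"{locus.chrom}\t{locus.start + 1}\t{locus.end}\t{locus.strand}"
                    f"\t{locus.gene_id}"
                    if locus
                    else ".\t.\t.\t.\t."
                )
                fh.write(
                    f"{c.query_id}\t{c.focus_species}\t{c.pattern}\t"
                    f"{c.origination_round}\t{loc}\n"
                )
    out.append(calls_path)
    return out


def stage_collapse(ctx: PipelineContext) -> list[Path]:
    _require(ctx, "calls", "collapse", "detect")
    config = ctx.config
    all_calls = [c for f in config.focus_species for c in ctx.calls.get(f, [])]
    cross_hits = [h for f in config.focus_species for h in ctx.hits.get(f, [])]
    ctx.fusion_set = collapse_orthologs(
        all_calls, cross_hits, config.params, config.species
    )
    path = ctx.out_dir / "fusion_clusters.tsv"
    with open(path, "w") as fh:
        fh.write("cluster\trepresentative\tspecies\tn_members\ttopology_consistent\n")
        for cl in ctx.fusion_set.clusters:
            consistent = topology_consistent(
                cl.species, config.phylogeny, config.focus_species
            )
            fh.write(
                f"{cl.cluster_id}\t{cl.representative.query_id}\t"
                f"{','.join(sorted(cl.species))}\t{len(cl.members)}\t"
                f"{int(consistent)}\n"
            )
    summary = shared_specific_table(ctx.fusion_set, config.focus_species)
    spath = ctx.out_dir / "summary_table.tsv"
    _write_summary_table(spath, summary, config)
    return [path, spath]


def _write_summary_table(path: Path, summary: dict, config: ControlConfig) -> None:
    with open(path, "w") as fh:
        fh.write("shared_species\tdetail_species\tgene_numbers\ttotal_gene_numbers\n")
        specific = summary["specific"]
        total_specific = sum(specific.values())
        for i, sp in enumerate(config.focus_species):
            label = "Species specific" if i == 0 else ""
            fh.write(f"{label}\t{sp}\t{specific.get(sp, 0)}\t")
            fh.write(f"{total_specific}\n" if i == 0 else "\n")
        by_combo = summary["by_combination"]
        for size in sorted(summary["shared_by"], reverse=True):
            first = True
            for combo, n in sorted(by_combo.items()):
                if len(combo) != size:
                    continue
                label = f"Shared by {size} species" if first else ""
                total = f"{summary['shared_by'][size]}" if first else ""
                fh.write(f"{label}\t{','.join(combo)}\t{n}\t{total}\n")
                first = False
        fh.write(f"Total\t\t\t{summary['total']}\n")


def stage_classify(ctx: PipelineContext) -> list[Path]:
    _require(ctx, "calls", "classify", "detect")
    config = ctx.config
    class_rows, retro_rows, te_rows = [], [], []
    for focus in config.focus_species:
        table = ctx.gene_table(focus)
        matrix = ctx.matrices[focus]
        te_trees = (
            read_te_annotation(config.path(focus, "te"))
            if config.has_path(focus, "te")
            else None
        )
        loci_for_te = []
        for call in ctx.calls[focus]:
            gene_id = table.gene_for(call.query_id) or call.query_id
            self_call = matrix[(call.query_id, focus)]
            parents = locate_parents(gene_id, self_call, table, call.locus)
            ctx.parents[(focus, call.query_id)] = parents
            other_loci = {}
            for sp in config.species:
                if sp == focus:
                    continue
                sp_table = ctx.gene_table(sp)
                loci = []
                for hit in matrix[(call.query_id, sp)].short_hits:
                    model = sp_table.model_for(hit.subject_id)
                    if model is not None:
                        loci.append(model.locus)
                other_loci[sp] = loci
            oc = classify_type(
                gene_id, call.locus, parents, other_loci, config.params.adjacency_kb
            )
            ctx.classes[(focus, call.query_id)] = oc
            class_rows.append(
                (
                    gene_id,
                    focus,
                    oc.type,
                    oc.subpattern,
                    oc.parents_in_focus,
                    ",".join(p.gene_id for p in oc.parents),
                    oc.notes,
                )
            )
            fusion_model = table.model_for(call.query_id)
            for parent in parents:
                parent_model = table.by_gene[parent.gene_id]
                span = parent.query_spans[0]
                flag = detect_retrofusion(fusion_model, parent_model, span)
                ctx.retro.setdefault((focus, call.query_id), []).append(flag)
                retro_rows.append(
                    (
                        gene_id,
                        focus,
                        parent.gene_id,
                        flag.parent_exon_count,
                        flag.fusion_span_exon_count,
                        int(flag.is_retro),
                    )
                )
            if call.locus:
                loci_for_te.append(call.locus)
        if te_trees is not None and loci_for_te:
            flags, count = te_overlap(loci_for_te, te_trees)
            for gid in sorted(flags):
                te_rows.append((gid, focus, int(flags[gid])))
    paths = []
    p = ctx.out_dir / "origination_classes.tsv"
    with open(p, "w") as fh:
        fh.write("gene\tspecies\ttype\tsubpattern\tparents_in_focus\tparents\tnotes\n")
        for row in class_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    paths.append(p)
    p = ctx.out_dir / "retro_flags.tsv"
    with open(p, "w") as fh:
        fh.write("gene\tspecies\tparent\tparent_exons\tspan_exons\tis_retro\n")
        for row in retro_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    paths.append(p)
    p = ctx.out_dir / "te_overlap.tsv"
    with open(p, "w") as fh:
        fh.write("gene\tspecies\tte_overlap\n")
        for row in te_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    paths.append(p)
    return paths


def stage_fixation(ctx: PipelineContext) -> list[Path]:
    _require(ctx, "calls", "fixation", "detect")
    config = ctx.config
    rows = []
    for focus in config.focus_species:
        if not (config.has_path(focus, "vcf") and config.has_path(focus, "genome")):
            continue
        genome = {
            rec.id: str(rec.seq)
            for rec in SeqIO.parse(str(config.path(focus, "genome")), "fasta")
        }
        _samples, variants, genotypes = read_population_vcf(config.path(focus, "vcf"))
        table = ctx.gene_table(focus)
        for call in ctx.calls[focus]:
            model = table.model_for(call.query_id)
            if model is None or model.chrom not in genome:
                continue
            exons = model.genomic_exons()
            keep = [
                i
                for i, v in enumerate(variants)
                if v.chrom == model.chrom
                and any(v.start < e and s < v.end for s, e in exons)
            ]
            result = fixation_frequency(
                model,
                genome[model.chrom],
                [variants[i] for i in keep],
                genotypes[keep, :],
                focus,
                config.params,
            )
            ctx.fixation[(focus, model.gene_id)] = result
            rows.append(result)
    path = ctx.out_dir / "fixation.tsv"
    with open(path, "w") as fh:
        fh.write("gene\tspecies\tn_individuals\tn_fixed\tfrequency\tfixed\n")
        for r in rows:
            fh.write(
                f"{r.gene_id}\t{r.species}\t{r.n_individuals}\t{r.n_fixed}\t"
                f"{r.frequency:.4f}\t{int(r.fixed_in_species)}\n"
            )
    return [path]


def stage_expression(ctx: PipelineContext) -> list[Path]:
    _require(ctx, "calls", "expression", "detect")
    config = ctx.config
    tissues = config.tissues
    profile_rows, corr_rows, class_rows, test_rows = [], [], [], []
    for focus in config.focus_species:
        if not config.has_path(focus, "fpkm"):
            continue
        records = read_fpkm_table(config.path(focus, "fpkm"))
        table = ctx.gene_table(focus)
        profiles = assign_fpkm(
            records, table.loci(), config.params.fpkm_overlap, tissues
        )
        expressed_fusions = []
        for call in ctx.calls[focus]:
            gene_id = table.gene_for(call.query_id) or call.query_id
            profile = profiles.get((gene_id, focus))
            if profile is None:
                continue
            profile_rows.append((gene_id, focus) + profile.fpkm)
            if not profile.expressed:
                continue
            expressed_fusions.append((gene_id, profile))
            parents = ctx.parents.get((focus, call.query_id))
            if parents is None:  # classify stage not run: fall back to self short hits
                parents = locate_parents(
                    gene_id, ctx.matrices[focus][(call.query_id, focus)], table,
                    call.locus,
                )
            parent_profiles = [
                profiles[(p.gene_id, focus)]
                for p in parents
                if (p.gene_id, focus) in profiles
            ]
            representative = representative_short_copy(parent_profiles)
            results = []
            for pp in parent_profiles:
                res = pearson_profile(gene_id, pp.gene_id, profile.fpkm, pp.fpkm)
                results.append(res)
                corr_rows.append(
                    (
                        gene_id,
                        focus,
                        pp.gene_id,
                        "NA" if res.r is None else f"{res.r:.4f}",
                        "NA" if res.p is None else f"{res.p:.4g}",
                        res.strength,
                    )
                )
            label = classify_pattern(profile, results)
            ctx.expression_classes[(focus, gene_id)] = label
            class_rows.append(
                (
                    gene_id,
                    focus,
                    label,
                    f"{profile.representative_level:.3f}",
                    "NA"
                    if representative is None
                    else f"{representative.representative_level:.3f}",
                )
            )
        counts = {
            t: sum(1 for _g, prof in expressed_fusions if prof.fpkm[i] > 0)
            for i, t in enumerate(tissues)
        }
        if expressed_fusions:
            from .expression import tissue_contingency

            pvals = tissue_contingency(counts, len(expressed_fusions))
            for (x, y), p in sorted(pvals.items()):
                test_rows.append((focus, x, y, counts[x], counts[y], f"{p:.4g}"))
    paths = []
    for name, header, rows in (
        (
            "expression_profiles.tsv",
            "gene\tspecies\t" + "\t".join(tissues),
            profile_rows,
        ),
        (
            "parent_correlations.tsv",
            "gene\tspecies\tparent\tr\tp\tstrength",
            corr_rows,
        ),
        (
            "pattern_classes.tsv",
            "gene\tspecies\tclass\tfusion_max_fpkm\tparent_max_fpkm",
            class_rows,
        ),
        (
            "tissue_tests.tsv",
            "species\ttissue_x\ttissue_y\tk_x\tk_y\tp",
            test_rows,
        ),
    ):
        p = ctx.out_dir / name
        with open(p, "w") as fh:
            fh.write(header + "\n")
            for row in rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        paths.append(p)
    return paths


def stage_report(ctx: PipelineContext) -> list[Path]:
    _require(ctx, "fusion_set", "report", "collapse")
    config = ctx.config
    summary = shared_specific_table(ctx.fusion_set, config.focus_species)
    n_specific = sum(summary["specific"].values())
    rate = birth_rate(n_specific, len(config.focus_species), config.divergence_my)
    lines = [
        "# Fusion gene detection summary",
        "",
        f"Unique fusion genes (ortholog clusters): {summary['total']}",
        f"Species-specific: {n_specific}",
    ]
    for sp in config.focus_species:
        lines.append(f"  - {sp}: {summary['specific'].get(sp, 0)}")
    for size, n in summary["shared_by"].items():
        lines.append(f"Shared by {size} species: {n}")
    lines += [
        "",
        f"Birth rate = {n_specific} specific / {len(config.focus_species)} species "
        f"/ {config.divergence_my} MY = {rate:.2f} per MY per species",
    ]
    if ctx.fixation:
        n_fixed = sum(1 for r in ctx.fixation.values() if r.fixed_in_species)
        fixed_rate = birth_rate(
            n_fixed, len(config.focus_species), config.divergence_my
        )
        lines.append(
            f"Fixed fusion genes (threshold "
            f"{config.params.fixation_threshold:.0%}): {n_fixed} "
            f"-> fixation rate {fixed_rate:.2f} per MY per species"
        )
    if ctx.expression_classes:
        counts: dict[str, int] = {}
        for label in ctx.expression_classes.values():
            counts[label] = counts.get(label, 0) + 1
        lines.append(
            "Expression classes: "
            + ", ".join(f"{k}={v}" for k, v in sorted(counts.items()))
        )
    path = ctx.out_dir / "summary.md"
    path.write_text("\n".join(lines) + "\n")
    return [path]


_STAGE_FUNCS = {
    "groups": stage_groups,
    "detect": stage_detect,
    "collapse": stage_collapse,
    "classify": stage_classify,
    "fixation": stage_fixation,
    "expression": stage_expression,
    "report": stage_report,
}


def run_pipeline(
    config: ControlConfig,
    out_dir: str | Path,
    stages: Sequence[str] | None = None,
) -> tuple[RunManifest, PipelineContext]:
    """Run the requested stages in dependency order and write a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if stages is None:
        stages = STAGE_ORDER
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise StageError(f"unknown stages: {unknown}; choose from {STAGE_ORDER}")
    ordered = [s for s in STAGE_ORDER if s in set(stages)]
    ctx = PipelineContext(config=config, out_dir=out_dir)
    inputs = {}
    for sp in config.species:
        for kind, p in config.paths.get(sp, {}).items():
            p = Path(p)
            if p.exists():
                inputs[f"{sp}:{kind}"] = _sha256(p)
    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(
                {
                    "species": config.species,
                    "focus": config.focus_species,
                    "outgroup": config.outgroup_species,
                    "params": vars(config.params) if hasattr(config.params, "__dict__") else str(config.params),
                },
                sort_keys=True,
                default=str,
            ).encode()
        ).hexdigest(),
        stages=list(ordered),
        inputs=inputs,
        version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    for stage in ordered:
        for path in _STAGE_FUNCS[stage](ctx):
            manifest.outputs[path.name] = _sha256(path)
    manifest.write(out_dir / "manifest.json")
    return manifest, ctx
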