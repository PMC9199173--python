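"""Run configuration, rooted phylogeny handling and in/mid/out group rounds.

A run is driven by a small structured control file naming the species, the
focus species (where fusion genes are searched), the fixed out-group species,
a rooted newick phylogeny, per-species file paths and numeric thresholds.

The detection scheme partitions the species into three groups per *round*:
the in-group starts as the focus species alone and grows along the phylogeny
by absorbing, each round, the sister leaf or sister clade of the smallest
clade containing the current in-group (skipping species assigned to the fixed
out-group); the mid-group is everything else.  Expansion stops when a single
mid-group species remains.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import dendropy
import yaml

from .errors import ConfigError, NewickError

__all__ = [
    "Parameters",
    "Phylogeny",
    "GroupRound",
    "ControlConfig",
    "parse_newick",
    "build_group_rounds",
    "parse_control",
    "load_control",
]

_FRACTION_FIELDS = (
    "long_cov",
    "short_min_cov",
    "short_total_cov",
    "fpkm_overlap",
    "fixation_threshold",
)


@dataclass(frozen=True)
class Parameters:
    """Numeric thresholds governing a run.

    Attributes
    ----------
    long_cov : float
        A hit covering strictly more than this fraction of the query protein
        is a *long homologous copy* (evidence the subject species carries the
        full, fused gene).
    short_min_cov : float
        A kept non-overlapping hit must cover strictly more than this
        fraction of the query to count as a *short homologous copy*.
    short_total_cov : float
        The union of short copies must cover strictly more than this fraction
        of the query for the species to be scored as "has short copies".
    min_short_copies : int
        Minimum number of short copies (distinct subject genes by default)
        required per species.
    ortholog_identity : float
        Percent identity above which two candidate fusion proteins from
        different focus species are collapsed as orthologs.
    ortholog_min_len : int
        Minimum aligned columns for the ortholog collapse rule.
    fpkm_overlap : float
        An expression record is assigned to a gene when the intersection
        covers strictly more than this fraction of the record.
    fixation_threshold : float
        A gene is called fixed in a species when the fraction of individuals
        with an intact fused ORF reaches this value.
    adjacency_kb : float
        Two loci on one chromosome closer than this (kb) are "adjacent" for
        origination sub-pattern classification.
    max_group_absent : int
        In a group of two or more species a copy may be missing from at most
        this many members and still be scored present.
    evalue_max : float
        Hits with a larger e-value are ignored before assortment.
    distinct_subjects : bool
        Count short copies per distinct subject gene (True) or per kept
        alignment span (False).
    """

    long_cov: float = 0.80
    short_min_cov: float = 0.20
    short_total_cov: float = 0.80
    min_short_copies: int = 2
    ortholog_identity: float = 80.0
    ortholog_min_len: int = 100
    fpkm_overlap: float = 0.50
    fixation_threshold: float = 0.80
    adjacency_kb: float = 100.0
    max_group_absent: int = 1
    evalue_max: float = 1e-5
    distinct_subjects: bool = True

    def __post_init__(self) -> None:
        for name in _FRACTION_FIELDS:
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ConfigError(f"parameter {name}={value!r} must be in (0, 1]")
        if self.min_short_copies < 1:
            raise ConfigError("min_short_copies must be >= 1")
        if self.ortholog_min_len < 1:
            raise ConfigError("ortholog_min_len must be >= 1")
        if self.max_group_absent < 0:
            raise ConfigError("max_group_absent must be >= 0")
        if self.adjacency_kb <= 0:
            raise ConfigError("adjacency_kb must be positive")
        if not 0.0 < self.ortholog_identity < 100.0:
            raise ConfigError("ortholog_identity must be a percent in (0, 100)")


class Phylogeny:
    """A rooted species tree with uniquely labelled leaves."""

    def __init__(self, tree: dendropy.Tree):
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        seen: set[str] = set()
        for label in labels:
            if label in seen:
                raise NewickError(f"duplicate leaf label {label!r}")
            seen.add(label)
        self._tree = tree
        self.leaf_labels: frozenset[str] = frozenset(labels)

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    def leaf_node(self, label: str) -> dendropy.Node:
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon.label == label:
                return leaf
        raise NewickError(f"species {label!r} is not a leaf of the phylogeny")

    @staticmethod
    def leaf_set(node: dendropy.Node) -> frozenset[str]:
        return frozenset(leaf.taxon.label for leaf in node.leaf_iter())

    def clade_leaf_sets(self) -> Iterator[frozenset[str]]:
        """Leaf sets of every node (leaves included)."""
        for node in self._tree.preorder_node_iter():
            yield self.leaf_set(node)

    def __contains__(self, label: str) -> bool:
        return label in self.leaf_labels


def parse_newick(text: str) -> Phylogeny:
    """Parse a rooted newick string into a :class:`Phylogeny`.

    The topology is taken as written; an explicit unrooted marker ``[&U]``
    is rejected because group expansion is root-dependent.
    """
    if "[&U]" in text or "[&u]" in text:
        raise NewickError("phylogeny must be rooted; unrooted marker [&U] found")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"could not parse newick: {exc}") from exc
    if tree.seed_node is None or not any(tree.leaf_node_iter()):
        raise NewickError("newick contains no leaves")
    return Phylogeny(tree)


@dataclass(frozen=True)
class GroupRound:
    """One in/mid/out partition of the species set."""

    index: int
    in_group: frozenset[str]
    mid_group: frozenset[str]
    out_group: frozenset[str]

    def all_species(self) -> frozenset[str]:
        return self.in_group | self.mid_group | self.out_group


def build_group_rounds(
    phylogeny: Phylogeny, focus: str, outgroup: Sequence[str]
) -> list[GroupRound]:
    """Generate the ordered in/mid/out rounds for one focus species.

    Round 1 has ``in_group == {focus}``.  Each later round absorbs the
    non-out-group leaves of the next enclosing clade (the sister leaf or
    sister clade of the current in-group; a multifurcation contributes all
    of its other children at once).  Clades made up entirely of out-group
    species are skipped.  Expansion stops once a single mid-group species
    remains, or as soon as a further step would empty the mid-group.
    """
    out = frozenset(outgroup)
    if focus in out:
        raise ConfigError(f"focus species {focus!r} is listed in the out-group")
    missing = ({focus} | out) - phylogeny.leaf_labels
    if missing:
        raise ConfigError(f"species not in phylogeny: {sorted(missing)}")
    non_out = phylogeny.leaf_labels - out
    mid0 = non_out - {focus}
    if not mid0:
        raise ConfigError(
            "no mid-group: at least one non-focus, non-out-group species is required"
        )
    rounds = [GroupRound(1, frozenset({focus}), frozenset(mid0), out)]
    in_set = frozenset({focus})
    node = phylogeny.leaf_node(focus)
    while len(rounds[-1].mid_group) > 1:
        node = node.parent_node
        if node is None:
            break
        candidate = Phylogeny.leaf_set(node) - in_set - out
        if not candidate:
            continue  # enclosing clade adds only out-group species: skip
        new_in = in_set | candidate
        mid = non_out - new_in
        if not mid:
            break  # expansion would leave no mid-group species
        in_set = new_in
        rounds.append(GroupRound(len(rounds) + 1, new_in, frozenset(mid), out))
    return rounds


@dataclass(frozen=True)
class ControlConfig:
    """A validated run configuration.

    ``species`` is ordered; the order is the priority used to pick cluster
    representatives.  ``paths`` maps each species to its input files
    (``proteins``, ``gff``, ``hits`` and optional ``genome``, ``vcf``,
    ``fpkm``, ``te``).
    """

    species: tuple[str, ...]
    focus_species: tuple[str, ...]
    outgroup_species: tuple[str, ...]
    phylogeny: Phylogeny
    paths: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    params: Parameters = field(default_factory=Parameters)
    divergence_my: float = 1.0
    tissues: tuple[str, ...] = ("root", "leaf", "panicle")

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ConfigError("duplicate species in configuration")
        focus, out = set(self.focus_species), set(self.outgroup_species)
        if focus & out:
            raise ConfigError(
                f"species cannot be both focus and out-group: {sorted(focus & out)}"
            )
        allsp = set(self.species)
        if not focus <= allsp or not out <= allsp:
            raise ConfigError("focus/out-group species must appear in the species list")
        if allsp != set(self.phylogeny.leaf_labels):
            only_cfg = sorted(allsp - self.phylogeny.leaf_labels)
            only_tree = sorted(self.phylogeny.leaf_labels - allsp)
            raise ConfigError(
                f"species list and phylogeny leaves differ "
                f"(config only: {only_cfg}, tree only: {only_tree})"
            )
        for f in self.focus_species:
            if not allsp - out - {f}:
                raise ConfigError(f"no mid-group species available for focus {f!r}")
        if self.paths:
            for sp in self.species:
                if sp not in self.paths:
                    raise ConfigError(f"no input paths configured for species {sp!r}")
        if self.divergence_my <= 0:
            raise ConfigError("divergence_my must be positive")

    def rounds_for(self, focus: str) -> list[GroupRound]:
        if focus not in self.focus_species:
            raise ConfigError(f"{focus!r} is not a focus species")
        return build_group_rounds(self.phylogeny, focus, self.outgroup_species)

    def path(self, species: str, kind: str) -> Path:
        try:
            return Path(self.paths[species][kind])
        except KeyError:
            raise ConfigError(f"no {kind!r} path configured for species {species!r}")

    def has_path(self, species: str, kind: str) -> bool:
        return species in self.paths and kind in self.paths[species]


def parse_control(text: str, base_dir: str | Path | None = None) -> ControlConfig:
    """Parse the YAML control file into a :class:`ControlConfig`.

    Recognized keys: ``species`` (ordered list), ``focus``, ``outgroup``,
    ``tree`` (newick text) or ``tree_file``, ``paths`` (per-species mapping),
    ``params``, ``divergence_my``, ``tissues``.  Relative paths are resolved
    against *base_dir* when given.
    """
    try:
        data = yaml.safe_load(io.StringIO(text))
    except yaml.YAMLError as exc:
        raise ConfigError(f"control file is not valid YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("control file must be a mapping of keys to values")
    for key in ("species", "focus", "outgroup"):
        if key not in data:
            raise ConfigError(f"control file is missing required key {key!r}")
    if "tree" in data:
        newick = str(data["tree"])
    elif "tree_file" in data:
        tree_path = Path(data["tree_file"])
        if base_dir is not None and not tree_path.is_absolute():
            tree_path = Path(base_dir) / tree_path
        newick = tree_path.read_text()
    else:
        raise ConfigError("control file must provide 'tree' or 'tree_file'")

    paths: dict[str, dict[str, str]] = {}
    for sp, mapping in (data.get("paths") or {}).items():
        if not isinstance(mapping, dict):
            raise ConfigError(f"paths entry for species {sp!r} must be a mapping")
        resolved = {}
        for kind, p in mapping.items():
            p = Path(p)
            if base_dir is not None and not p.is_absolute():
                p = Path(base_dir) / p
            resolved[str(kind)] = str(p)
        paths[str(sp)] = resolved

    params = Parameters(**(data.get("params") or {}))
    return ControlConfig(
        species=tuple(str(s) for s in data["species"]),
        focus_species=tuple(str(s) for s in data["focus"]),
        outgroup_species=tuple(str(s) for s in data["outgroup"]),
        phylogeny=parse_newick(newick),
        paths=paths,
        params=params,
        divergence_my=float(data.get("divergence_my", 1.0)),
        tissues=tuple(data.get("tissues", ("root", "leaf", "panicle"))),
    )


def load_control(path: str | Path) -> ControlConfig:
    """Read and parse a control file, resolving paths against its directory."""
    path = Path(path)
    return parse_control(path.read_text(), base_dir=path.parent)
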