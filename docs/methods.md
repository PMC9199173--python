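# Methods

## The detection model

A fusion (chimeric) gene carries sequence derived from two independent
parental genes in one coding unit.  Detection rests on a presence–absence
argument over a rooted species phylogeny rather than on any single genome:
the fused ("long") form should exist only in the clade descending from the
branch on which the fusion arose, while the parental ("short") forms should
persist in species outside it.  Out-group support is what separates a
fusion (short copies ancestral, long copy derived) from a fission (the
reverse).

### Hit assortment

All evidence comes from standard 12-column tabular protein alignment output
(qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore) of each focus species' proteins against every species'
proteome, including its own.  For one query and one subject species:

1. hits with query-span coverage strictly greater than `long_cov` (default
   0.80) are long homologous copies;
2. the remaining hits are sorted by query span (descending; ties by bit
   score descending, subject id, then coordinates — making the result
   independent of input order) and kept greedily when they overlap no
   already-kept hit by even one residue;
3. kept hits covering strictly more than `short_min_cov` (default 0.20) are
   short homologous copies;
4. the species "has short copies" when at least `min_short_copies`
   (default 2) distinct subject genes remain and their union covers more
   than `short_total_cov` (default 0.80) of the query.

Coverage is measured on the query as (qend − qstart + 1)/query length,
ignoring alignment gaps.  The query's hit to itself is the trivial long
copy and never a short-copy candidate; otherwise every gene would
self-fuse.  Hits with e-value above `evalue_max` (default 1e-5) are ignored
— the admission threshold is exposed because alignment tools are run
outside the package.  Counting short copies per distinct subject gene
(rather than per kept span) is the default because a fusion needs two
parents; `distinct_subjects=False` restores per-span counting.

### Group rounds and pattern calling

Round 1 sets the in-group to the focus species alone; each later round
absorbs the sister leaf or sister clade of the smallest clade containing
the current in-group (a multifurcation contributes all sisters at once;
clades consisting only of fixed out-group species are skipped).  Expansion
stops when one mid-group species remains, or earlier if absorbing the next
clade would empty the mid-group (possible when a large clade is added as a
unit; the final round then has a larger mid-group and is still evaluated).

Group presence tolerates absence in at most `max_group_absent` (default 1)
members of any group of ≥ 2 species, absorbing assembly and annotation
imperfections.  For a two-species group this makes presence equivalent to
"present in at least one member"; the rule is implemented exactly as
stated.  Of the 64 joint (L, S) presence combinations, three are accepted:
L-110 & S-111, L-100 & S-111, L-100 & S-110.  When several rounds match,
the smallest round (most recent origination consistent with the data) is
reported.  Because one absence is tolerated in larger groups, small
in-groups usually match whenever larger ones do, so shared fusions also
tend to be reported at round 1; the cluster species set, not the round, is
what carries the sharing information.

### Ortholog collapse and accounting

Candidate fusion proteins from different focus species are collapsed with a
graph: an edge joins two candidates when any hit between them exceeds
`ortholog_identity` (80%) identity over at least `ortholog_min_len` aligned
columns; clusters are connected components (transitive closure).  The
published rule says "100 bp"; since candidates are proteins this package
defaults to 100 aligned amino-acid columns and leaves the value
configurable.  Cluster species sets are checked for topology consistency:
the set must equal the focus-species restriction of some clade's leaf set
(single origination, no losses).

### Origination classification

Parents detectable in the focus genome are the distinct subject genes of
the query's own-species short hits, excluding the fusion gene itself and
genes overlapping its locus.  Type I/II/III = both/one/no parents
detectable.  Sub-patterns use an adjacency threshold (`adjacency_kb`,
default 100 kb, same chromosome; the source analyses relied on manual
synteny inspection, so any fixed number is a package choice): A = parents
and fusion all within the threshold; C = exactly one parent adjacent;
B = otherwise; E/D = surviving parent adjacent / not; G/F = the lost
parents' homologs co-located (within the threshold in at least one other
species, a positional stand-in for synteny blocks) / dispersed.

A retro-fusion contribution is structural: the parental span, mapped onto
the fusion CDS at 3 nt per residue cumulatively over 5'→3' exons, falls
inside exactly one fusion CDS exon while the parent itself has ≥ 2 CDS
exons — i.e. the parent's introns were lost, the signature of
retroposition from mRNA.

### Population fixation

For each fusion gene and individual, the reference CDS is rebuilt from the
genome and gene model, the individual's alternate alleles (substitutions
and indels; multi-allelic records must be split upstream) are substituted
with genomic→CDS coordinate mapping honouring strand, and the reading
frame is checked: intact iff length ≡ 0 (mod 3) and no premature stop
(codons containing N are never called stops).  An individual carries a
variant with any alt allele (het or hom; `hom_only` restricts to
homozygotes); individuals with a missing genotype at any site of the gene
leave the denominator.  Start-codon loss is not counted as disruption —
only frame change and stop gain are.  The fixation frequency is the intact
fraction; the gene is fixed in the species at ≥ `fixation_threshold`
(0.80).  Rate estimators are deliberately plain arithmetic:
species-specific count / species number / divergence time (divergence is a
user-supplied constant, default 1 MY); age from synonymous divergence as
Ks/(2μ); genes / age.

### Expression

An FPKM record is assigned to a gene when the intersection covers strictly
more than `fpkm_overlap` (0.50) of the *record* (the record is the unit
being attributed; a gene-length denominator is available).  Multiple
records for one gene and tissue reduce by maximum, as does the
representative over a gene's several short copies and over tissues.
Fusion-vs-parent profiles are compared by Pearson correlation with the
two-sided t test (t = r·√((n−2)/(1−r²)), df = n−2); with the default three
tissues df = 1, so "strong" (p < 0.05) effectively demands |r| ≳ 0.997 —
with so few points the test has power only for near-exact profile copies,
which is why profiles pooled across species can be supplied instead.
Zero-variance profiles give an undefined correlation and are excluded
rather than failing.  Classes: parental-like (≥ 1 strong parent), novel
(parents with data, none strong), no-parent-data.  Tissue-wise expressed
counts are compared pairwise with two-sided Fisher exact tests on
[[k_x, n−k_x], [k_y, n−k_y]].

## The simulator

`fusionscan.simulate` emulates the data regime end to end.  Background
proteins (default 60 per genome, lengths uniform on 80–240 residues over a
uniform 20-letter alphabet) evolve down the tree by i.i.d. substitutions
(default 0.02 per residue per branch); substitutions only, no indels, so
true homologous spans stay exact and hits can be synthesized from the known
homology map instead of running an aligner (identity = 1 − substitution
distance).  The default ten-species tree has four focus species in two
sister pairs, three laddered mid-group species and three out-group species,
giving five detection rounds from the first focus species — the shape of a
recently diverged species group with progressively distant relatives.

A planted event concatenates two parental proteins on a chosen branch.
Parent deletion in a subset of carrier species creates Type II/III cases;
the plan validator rejects events that the detector's own rules make
invisible (e.g. a species-specific fusion whose parent is deleted in that
same species leaves no in-group short-copy evidence).  Placement modes
(`dispersed`, `same_region`, `near_one`) control genomic layout — 20 kb
default spacing vs 2 kb deliberate adjacency, with `adjacency_kb = 10`
written into generated configs to match that scale — and therefore the
expected sub-pattern.  Retro events give parent A three CDS exons and the
fusion one; non-retro fusions get two exons split inside the parent-A half
and single-exon parents, so no spurious retro flags arise.  Genomes are
reverse-translated with one fixed codon per amino acid (several codons are
one substitution from a stop, which the population generator exploits to
plant premature-stop SNPs; a gene with no such codon receives a 1-bp
frameshift deletion instead).  Each individual is an independent Bernoulli
draw at the disruption probability, recorded homozygous, plus one benign
segregating substitution in a different codon.  FPKM modes: parental-like
copies a present parent's profile (×0.5, zero noise by default — required
for a strong call at df = 1), novel re-samples until |r| ≤ 0.9 against
every present parent, silent emits zeros.

What the generator does **not** emulate: indels and rearrangements in
background evolution, paralogous gene families and tandem arrays, codon
usage and realistic intergenic sequence, linkage between variant sites,
annotation errors, and expression noise across replicates.  Passing the
planted-recovery tests therefore demonstrates the correctness of the
decision logic on data satisfying the method's assumptions, not robustness
to real-genome annotation artifacts — the published robustness analysis
across annotation versions has no desk-scale counterpart.

## Numerical and design choices

* All thresholds are strict inequalities (coverage exactly 0.80 is not
  long; 0.20 is not a short copy; 0.50 record overlap is not assigned).
* Coordinates are 1-based inclusive in files (tabular hits, GFF3, VCF,
  FPKM), 0-based half-open in memory; BED TE annotations are honoured as
  0-based half-open.
* Determinism: hit assortment sorts with full tie-breaks; cluster
  representatives are chosen by configured species priority then gene id;
  simulator outputs are a pure function of the plan, with independent
  seeded streams per concern (sequences, genomes, population, expression).
* Degenerate inputs: empty groups, zero individuals, zero-length queries,
  unknown subjects and out-of-bounds coordinates raise typed errors; an
  unknown TE chromosome or annotation-missing parent warns and degrades
  (zero overlap / parent undetectable).
* Benchmarks at desk scale: the acceptance checks run on bundles of 60
  background genes, 8 planted events (Types I/II/III, one retro), 10
  species, and populations of 200 individuals — sizes chosen so the full
  suite completes in seconds while every code path is exercised.

## Known limitations

* The earliest-round convention reports the most recent origination
  consistent with the data; distinguishing a shared origination from
  parallel gains or losses is delegated to the cluster-level topology
  check, mirroring the method's own accounting.
* Synteny for Type III F/G is positional co-location, not whole-genome
  synteny blocks.
* Ks values are inputs, not computed from alignments; divergence times are
  user-supplied constants.
* cDNA-level fusion (transcript read-through without genomic fusion) is
  out of scope: only annotated protein-coding genes are considered.
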