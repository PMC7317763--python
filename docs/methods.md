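# Methods

## Data model and assumptions

A phylome is a collection of per-gene trees, each built for one *seed* gene
of the hybrid, with branch lengths in substitutions/site and (where the tree
builder emitted them) internal-node supports in [0, 1]. Every leaf maps
through a taxonomy table to a species and a taxonomic *section*; the method
assumes each candidate progenitor section is represented by one diploid
species. The underlying alignment of each tree is an in-frame nucleotide
MSA over {A, C, G, T, N, -} whose width is a multiple of three, frame
anchored at the first column. Supports given as percentages in (1, 100] are
divided by 100 at parse time (logged); unlabeled internal nodes carry a
*missing* support, never a silent 1.0, and a missing support always fails a
support threshold.

## Quality control

Rows whose undetermined fraction — N count over **ungapped** length, since
gap columns are artifacts of the alignment rather than sequence content —
strictly exceeds the threshold are removed, mirroring a ">1%" rule with two
presets: 0.01 for CSL extraction and dating, 0.10 for subgenome assignment.
Pruned trees keep their geometry: branch lengths of suppressed unifurcations
are summed so patristic distances among the survivors are unchanged (tested
to 1e-9). Removing the seed row marks the tree unusable rather than raising;
unusable trees are excluded from every downstream tally. Trees with fewer
than five distinct species (species, not leaves) are discarded.

## CSL extraction and the parental census

For CSL extraction a tree must be rooted. Trees parsed with a bifurcating
root are taken as rooted; otherwise the tree is rooted on the edge above the
configured outgroup-section leaf (MRCA edge when the outgroup has several
leaves, falling back to the nearest single leaf when the outgroup is not
monophyletic), else midpoint-rooted. The policy is logged per tree. Note
that re-rooting keeps support values attached to nodes, the usual—and for
supports near the root slightly lossy—convention.

The CSL search ascends from the seed leaf to the first ancestor whose other
child subtree contains at least one non-seed-species leaf; seed-species
paralogs in the immediate sister position are thereby skipped. The CSL
distance is the minimum patristic distance from the seed to a
non-seed-species leaf of that sister group, and the MRCA support is the
support of that first-ascent node (also when a multi-section sister subtree
is later resolved to a single leaf; the per-leaf distances are kept in the
record for auditing). Mixed-section sister groups resolve to the section of
the minimum-distance leaf; exact ties break lexicographically by gene id and
are logged.

The four validity filters (≥5 species, ≤3 sister-group species, distance
≤0.1 substitutions/site, support ≥0.9) are all inclusive, reading "at
most"/"at least" literally, and each criterion's outcome is reported
separately so per-filter attrition can be reconstructed. The census counts
resolved sections over passing trees; the top two (ties broken
lexicographically for determinism) are the nominated parental pair, with the
more frequent section taken as maternal — in old hybrids fractionation tends
to spare the maternal subgenome, and the final call should in any case rest
on independent evidence such as plastid markers.

## 4D sites and dating

The eight four-fold degenerate codon families (TC\*, CT\*, CC\*, CG\*, AC\*,
GT\*, GC\*, GG\*) are derived from the standard genetic code at import time.
A third-codon column counts as a shared 4D site iff both rows have ungapped,
non-N, identical first two positions forming such a family; third positions
with N or a gap in either row are listed separately and excluded from
counting. A↔G and C↔T differences are transitions, all others
transversions. `d4 = (ti+tv)/n_4D` is a raw p-distance: no multiple-hit
correction is applied, a deliberate choice that introduces a known downward
bias of order `d4²` (≈2–3% at the distances the retention filters admit,
growing for older events).

Ratios and dates are retained only when `ti+tv ≥ 5` and the seed–CSL tree
distance is at most `max_csl_distance_for_4dtv`. The default cap is 0.05
substitutions/site; 0.5 is the documented permissive alternative, reachable
in `DatingConfig` and on the command line, and switching between them is
always an explicit, logged configuration choice. Divergence time is
`d4 / (2 · rate · generations_per_year)`, scaled to million years. Defaults:
`rate = 5e-9` substitutions/position/generation (a standard value for plant
nuclear genes) and `generations_per_year = 1` (annual life history), making
the rate effectively per year.

Distributions (per section, and pooled over the two parental sections) are
summarised by the mode of a Gaussian KDE (Silverman bandwidth via scipy,
512-point grid spanning the data; degenerate zero-spread samples short-
circuit to their common value) and by the arithmetic mean. **Estimator
caution:** with ~230 4D sites per gene the per-gene date carries ~30%
counting noise with positive skew, so the KDE mode of the per-gene
distribution is an unstable statistic — across simulation seeds it wanders
roughly ±10% around the true age, while the arithmetic mean is stable to a
few percent. Both are always reported; conclusions should weigh the mean.

## Subgenome assignment

Candidate leaves of either parental section are ranked by patristic distance
from the seed. A leaf qualifies when the support of the node it attaches to
(its parent node) is at least 0.9; if the nearest parental leaf fails, the
next-nearest qualifying one is used, and the support actually used is
recorded in the output. An exact distance tie between qualifying leaves of
the two different sections leaves the gene orphan (logged): refusing is
safer than guessing.

Orphan rescue is a single, non-chaining pass in coordinate order: a rescued
gene never serves as evidence, because only tree-provenance assignments of
the upstream/downstream neighbour count. Both neighbours concordant, or
exactly one neighbour assigned (including terminal genes with their single
neighbour), transfer the origin; discordant neighbours leave the gene
orphan. The pass is therefore idempotent, and gene counts are conserved —
origins only ever move from orphan to parental.

Scaffolds take an origin when, among their parentally assigned genes
(orphans ignored), the most frequent origin reaches the majority fraction
(default 0.75, inclusive; the rule applies unchanged to single-gene
scaffolds). Scaffolds with no parentally assigned gene are orphan; gene-less
scaffolds are excluded from the table. The summary reports, per origin and
in total, scaffold count, summed length, length fraction (%, one decimal),
mean scaffold length and mean genes per scaffold; scaffolds without a known
length are counted but excluded from length sums with a warning.

## Synthetic phylomes

The generator emulates the data situation the pipeline is built for: six
diploid sections on an ultrametric ladder — parental split 6.5 MyA, further
sections joining at 7.5, 9, 10.5 and 15 MyA — and a hybrid seed species
whose single retained copy per gene attaches to the maternal lineage with
probability 0.54 (a fractionation bias matching the maternal/paternal gene
imbalance such hybrids show) or else the paternal lineage, at the
hybridization time (default 4.9 MyA). With probability 0.23 both
parental-section leaves are dropped, emulating orphan trees. Defaults of
2,000 genes of 450 codons reflect a desk-scale phylome with realistic
per-gene information content (mean CDS ≈1.4 kb).

Sequences evolve site-wise under a two-parameter (Kimura) process with
Ti/Tv rate ratio κ = 2: third positions of root codons in 4D families evolve
at the neutral rate (5e-9/site/year), all other positions at 0.2× that; the
rate class of a site is fixed along the tree. The root sequence is uniform
over the 61 sense codons, so all eight 4D families are represented in
expectation. At small divergence the expected 4DTv ratio is the closed form
2/(κ+2) = 0.5, and the seed-to-parental-leaf expectation of d4 is the 2rT
clock (both are asserted in the tests). Emitted gene-tree branch lengths are
the true expected lengths perturbed by mean-one lognormal noise (σ = 0.05),
modelling tree-estimation error; the alignments themselves evolve along the
true lengths, so the emitted branch noise exercises the distance filters
without biasing the clock. Internal supports are drawn from U(0.95, 1) by
default, degradable via configuration, since only threshold behaviour needs
controlling.

Genes are packed onto scaffolds (Poisson around 10 genes per scaffold,
minimum 1); along a scaffold the current subgenome switches with probability
`switch_prob` (0 gives monomorphic scaffolds, 0.5 full intermixing), drawing
genes from per-origin pools so the per-gene truth is preserved. Coordinates
are 1-based and non-overlapping with 1 kb intergenic spacing; scaffold truth
is the majority of its genes' true origins, ties toward the
lexicographically smaller section.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: incomplete lineage sorting and
introgression (gene trees here always match the species history up to
noise), paralogy and gene duplication, indels and alignment error (the 1%/
10% N-cleaning paths are exercised by injecting N runs post hoc with
`corrupt()`), rate variation among genes and lineages, and estimated (rather
than drawn) support values. A fixed seed makes every output byte-identical.

## Pipeline and bookkeeping

Every stage logs its thresholds and per-filter attrition (input, seed
removed, species-filter failures, no-CSL, extracted, passing), and the per-
stage counts are internally consistent by construction. The `all` driver
shares the parsed trees between stages in memory; at desk scale re-parsing
is cheap enough that no on-disk intermediate cache is kept. Test and
acceptance problem sizes (300-gene suites, one 2,000-gene recovery run) are
chosen to keep a full run in tens of seconds on one core while leaving the
statistical assertions well-powered.

## Known limitations

- No multiple-hit correction on d4; raw p-distance dating is downward-biased
  for old events.
- The KDE-mode "peak" is noisy at realistic per-gene information content
  (see above); the mean is the stable summary.
- Re-rooting unrooted trees keeps supports attached to nodes, which can
  misattribute the support of the edge crossing the new root.
- Neighbour rescue trusts annotation order; assembly errors that shuffle
  gene order propagate into orphan assignments.
- One diploid species per section is assumed throughout; denser taxon
  sampling would need the census and parental-leaf rules generalised.
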