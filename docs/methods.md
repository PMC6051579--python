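# Methods

This note documents the models, rules and numerical choices behind
`ganokit`, and what the synthetic-data validation does and does not show.

## Species vocabulary and character model

Thirteen laccate Ganodermataceae taxa are treated for the United States
(twelve species plus the forma specialis *G. curtisii* f.sp. *meredithiae*,
a slow-growing pine-decay variant carried separately because it keys out on
physiology). A specimen is described by a `CharacterProfile`: context-tissue
color class (white / buff / dark brown), melanoid deposits, concentric
growth zones, contextual and in-culture chlamydospores, stipe habit
(stipitate / pseudostipitate / sessile), hymenium pore density (pores/mm,
an interval), host group (hardwood / conifer / monocot / cycad / cactus),
region, in-vitro growth-rate class (fast ≈ 6 mm/day vs slow < 3 mm/day on
malt extract agar) and mean basidiospore length and width in µm.

Missing data is a first-class state (`missing` for categoricals, `None` for
numerics), never an empty string: the key engine must distinguish "observed
absent" from "not observed". Free-text context colors are mapped to the
three classes by an editable shipped synonym table of Ridgway-style names;
unmapped terms raise rather than guess, since silent mis-binning of a color
term would corrupt every downstream identification.

Survey tallies report percentages rounded half-away-from-zero, at integer
precision by default with a one-decimal mode for rare classes (a 1-in-298
host class is 0% at integer precision but 0.3% at one decimal). Over any
complete partition the rounded percentages sum to 100 within half a point
per class.

## Key engine

The 12-couplet dichotomous key is data, not code: each couplet has two
leads, each lead a conjunction of atomic predicates (equality, set
membership, or a closed numeric range for spore dimensions) plus a target
(another couplet or a species). Loading validates the structure — exactly
two leads, no cycles, no dangling references, all 13 taxa reachable from
couplet 1.

Traversal uses three-valued logic. A lead over a missing character is
*unknown*; a couplet follows a single lead only when exactly one lead is
definitely true and the other definitely false, and otherwise follows both.
This covers three deliberate cases: missing characters, measurements
falling outside all sibling ranges (the printed spore ranges overlap, so a
hard failure would be wrong), and malformed keys. Consequences that are
tested as invariants: every identification returns ≥ 1 candidate; each
reference profile identifies exactly its own taxon; the empty profile
returns all 13; and removing a character never shrinks the candidate set.

Spore-size predicates use the printed per-taxon (min–max) ranges with
closed endpoints. The *G. lucidum* lead accepts `region` of either the
documented restricted Utah/California populations or `western_US`
generally, since introduced populations may spread. "Tropical" key leads
are matched by the `subtropical` region class (south Florida / south
Texas). Couplet 6 separates *G. curtisii* from its forma specialis on
growth-rate class alone, mirroring the physiological diagnosis.

`distinguishing_characters(a, b)` walks both species' key paths and reports
the characters in the symmetric difference of the two leads at the first
diverging couplet (atoms shared by both leads, e.g. "on conifers" at the
*G. tsugae* / *G. oregonense* couplet, are not separating).

## Spore morphometrics

SSI = 100·width/length and Q = length/width are computed **per spore** and
averaged; the reciprocal identity SSI·Q = 100 holds exactly per spore but
*not* for averages of ratios, which is why taxon summaries never report the
ratio of mean dimensions. Published taxon means are averages of unpublished
per-spore data, so the package asserts equality with printed values only
where the ratio of printed means coincides at table rounding (it does for
*G. curtisii*: 10.6/6.4 µm → SSI 60.4, Q 1.7). Display rounding is one
decimal, half away from zero. Tukey-style means-separation letters are not
computed (the per-spore raw data behind them is not available); the report
renderer accepts externally supplied letters verbatim.

## Desk-scale phylogenetics

The sequence stage substitutes distances + neighbor joining + nonparametric
bootstrap for heavyweight ML/Bayesian tree inference. This is a scope
decision: the scoring scheme consumes *any* support-annotated tree, and
Newick input (supports as internal node labels, or comment-embedded via a
flag; unlabeled nodes mean *absent* support, not 0) lets externally
computed ML trees be scored with the same machinery.

* **Concatenation**: loci are concatenated in input order; taxa absent from
  a locus are padded with `?`; the partition table is 1-based inclusive
  (`DNA, ITS = 1-521`), converted internally to 0-based half-open. Slicing
  the supermatrix by partition reproduces each input for shared taxa.
* **Distances**: pairwise deletion — only columns with both residues in
  {A,C,G,T} are compared, so `?` padding degrades rather than destroys
  partial-taxon distances. p is the mismatch proportion; JC69 is
  −(3/4)·ln(1−4p/3), defined for p < 3/4 (saturation raises); K2P is
  −½·ln((1−2P−Q)·√(1−2Q)) with P, Q the transition and transversion
  proportions. Pair counts are computed by indicator-matrix products, so a
  full bootstrap over a ~60 × 2470 supermatrix takes seconds.
* **Neighbor joining**: classic Saitou–Nei Q-criterion. Ties in Q (within a
  1e-9 relative tolerance) are broken by joining the lexicographically
  smallest label pair, a merged node inheriting its smallest tip label —
  this makes the topology a pure function of the labelled matrix,
  independent of row order. Negative branch-length estimates are clamped to
  zero with the deficit moved to the sister edge, preserving the joined
  pair's path length. On additive matrices the generating topology and
  branch lengths are recovered exactly (tested on random trees ≤ 12 tips,
  and cross-checked against an independent NJ implementation).
* **Bootstrap**: resample columns with replacement, NJ per replicate,
  support = percentage of replicates containing each full-tree bipartition.
  One RNG stream per run from a single integer seed; supports are
  reproducible under the seed and invariant to taxon input order.
* **Rooting**: the root is placed midway on the branch subtending a
  declared monophyletic outgroup (two *Tomophagus*-style isolates in the
  synthetic default); supports are reattached by bipartition, so rerooting
  cannot shuffle them.
* **Congruence**: trees are projected onto their shared taxa; two splits
  conflict when both meet the support floor and fail the four-intersection
  compatibility test. An empty report means the loci tell no
  well-supported conflicting stories — the precondition for concatenating.

## Barcode-locus scoring

For each species on a support tree: absent → *not tested* (absence must be
explicit in the taxon map; unmapped tips are an error); one tip →
*resolved, unscored*; ≥ 2 tips forming a bipartition clade with support ≥
the floor → *supported* (score = that support); monophyletic but below the
floor → *below threshold*; monophyletic without a support annotation, or
non-monophyletic → *not resolved*. Monophyly is assessed in the unrooted
(bipartition) sense after excluding declared outgroup tips, so a species
straddling the root-adjacent bipartition is still one clade.

Locus summary: **number of terminal clades** = supported + resolved-unscored
(single-sample lineages must count, or the published clade totals cannot be
reached); **total score** = Σ supports of supported clades only. A
below-floor clade contributes to neither. The floor is applied as ≥ 75
although it is conventionally quoted as "> 75%": no published support value
equals 75 exactly, so both readings reproduce the published table, and the
closed form is simpler. The published comparison table prints two codes for
unscored-but-resolved lineages (R\* and NR\*); both are read as
resolved-unscored, which is required for the printed clade counts to be
self-consistent. One published prose total for tef1α (1070) disagrees with
both the printed table total and the sum of its cells (970); the cells
govern. A posterior-probability floor (default 95) is applied only when a
second support annotation is supplied; the in-repo bootstrap produces only
bootstrap-style supports. Ranking is by (clade count, total score)
descending, alphabetical on full ties.

## Synthetic data

The generator's defaults are the study conditions: 13 species, 1–8 tips
each, a designated two-tip outgroup species, four loci of 521/764/615/570
columns, between-species divergence 0.15 expected substitutions/site
(sister species separated by ~0.15, each species-level edge jittered
uniform [0.5, 1.5]× to avoid degenerate ultrametric ties) and
within-species depth 0.005. Sequences evolve under Jukes–Cantor — the same
model the default distance assumes, so the estimator is correctly
specified; simulating JC and estimating K2P is an available mismatch
experiment, not the default. Spore tables are truncated normals on the
published per-taxon (min–max) ranges with sd = (range)/4, which keeps ~95%
of the untruncated mass in range; sampled widths are capped at the sampled
length. Character profiles are the reference profiles with characters
independently masked at a configurable noise rate. All randomness derives
from one integer seed through named substreams (tree, sequences, spores,
profiles), so components regenerate independently.

What passing recovery tests show: the pipeline correctly extracts planted,
cleanly separated species structure (every multi-tip species supported at
the 75 floor with 100 bootstrap replicates; the concatenated matrix, with
the most columns, ranks first). What they do not show: robustness to real
data's alignment error, rate heterogeneity, indels, recombination or
gene-tree/species-tree discordance — none of which the generator emulates.

## Problem sizes and determinism

Default validation scale: ~60 tips × 2470 columns, 100 bootstrap
replicates per analysis (five analyses: four loci plus the concatenation),
chosen as the point where planted-clade supports saturate; the full suite
runs in well under a minute of compute for the phylogenetic stage.
Exhaustive oracles run where enumeration is cheap (all unrooted topologies
≤ 6 tips for monophyly; 100 random additive matrices ≤ 12 tips for NJ).
Everything stochastic is seeded; pipeline manifests record SHA-256
checksums of every output, and rerunning with the same seed reproduces
them bit-for-bit.

## Known limitations

* NJ is statistically consistent but not maximum likelihood; very short
  internal edges can receive modest support that ML might resolve.
  Externally inferred trees can be supplied in Newick wherever a
  `SupportTree` is accepted.
* The key engine is deliberately non-probabilistic: it returns candidate
  sets, not posterior probabilities.
* JC69/K2P distances assume no rate heterogeneity across sites.
* The printed-table scoring ships the published support values as data;
  re-deriving them from sequences requires the original GenBank/TreeBase
  material and ML inference, both outside this package's scope.
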