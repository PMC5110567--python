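# Methods

## Problem and scope

`barcodegap` evaluates how well DNA barcode markers — singly and in
multi-locus combination — distinguish species (or higher groups such as
taxonomic sections) in a sampled clade. The package targets the classical
plant-barcoding design: a few chloroplast loci (e.g. *rbcL*, *matK*,
*trnS*-*trnG*) plus the nuclear ITS spacer, several conspecific individuals
per species, and two complementary success criteria:

1. **Pairwise-distance gap criterion.** A group is discriminated when the
   minimum inter-group distance involving it is strictly larger than its
   maximum intra-group distance (a per-group barcoding gap). The criterion
   defaults to the uncorrected p-distance; the K2P-corrected distance is
   available via a flag.
2. **Tree criterion.** A group is discriminated when its individuals form a
   monophyletic group on the neighbor-joining tree (K2P distances) and the
   subtending edge's nonparametric bootstrap support strictly exceeds a
   threshold (default 0.5).

The *discrimination rate* of a marker set is the percentage of non-excluded
groups that pass a criterion.

## Distances

For each pair of rows, alignment columns are classified under **pairwise
deletion**: a column counts only if both rows carry an unambiguous A/C/G/T;
gaps, `N` and IUPAC ambiguity codes are skipped for that pair alone
(`deletion="complete"` instead removes every column containing any
non-ACGT character, for compatibility with complete-deletion conventions).
With transition proportion `P` and transversion proportion `Q`,

* p-distance: `p = P + Q`
* Kimura two-parameter: `d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)`

A pair with zero comparable columns, or with a non-positive K2P logarithm
argument (saturation), is *undefined*: stored as NaN, excluded from means,
minima, maxima and histograms, and tallied in the run log — never clamped
to a large constant. Pipelines that need a complete matrix (NJ) raise on
undefined entries rather than imputing silently.

Internally all pairwise column classifications are precomputed once per
alignment as indicator arrays, so a distance matrix under any column
multiplicity vector is three matrix–vector products; this is what makes a
1000-replicate bootstrap cheap (an 85-taxon, 1.8-kb concatenation runs in
seconds).

## Neighbor joining and bootstrap

NJ follows the standard agglomeration: join the pair minimising
`Q(i,j) = (n-2) d(i,j) - r_i - r_j`, branch lengths from the usual split
formula, new node distances by the reduction formula. Two numerical
choices matter:

* **Tie-breaking** in the Q minimisation is the lexicographically smallest
  `(i, j)` index pair in the current matrix, making runs bit-for-bit
  reproducible.
* **Negative branch lengths are kept as computed.** This preserves exact
  recovery of additive matrices (verified against an exhaustive
  topology-enumeration + least-squares oracle for up to six taxa); a
  clamp-to-zero option exists in the newick writer for display.

Bootstrap resamples alignment *columns* with replacement (seeded),
recomputes distances and the NJ tree per replicate, and scores each
internal edge of the reference tree by the fraction of replicates whose
tree contains the same leaf-set bipartition. Replicates whose resampled
matrix has undefined entries are skipped and tallied; supports are
fractions of the effective replicate count. Terminal edges carry support
1.0 by definition.

Monophyly is tested on the **unrooted** tree through bipartitions (no
outgroup or rooting is assumed): a group is monophyletic iff some edge
splits exactly that group from everything else.

## Singletons and denominators

A species sampled once has no intra-group distance, so the gap criterion is
untestable for it; it is also trivially monophyletic in any tree. The
default policy excludes singletons from both criteria's denominators,
keeping the two rates comparable; `singleton_policy="zero_intra"` instead
scores a singleton's intra distance as zero (some barcoding studies do
this). Strict inequalities are used in both criteria, so ties (equal gap
bounds, or support exactly at the threshold) fail.

## Alignment statistics

* A **variable site (SNP)** is a column where at least two distinct
  unambiguous nucleotides occur; gaps and ambiguity codes never create
  polymorphism (conservative, substitution-only counting).
* An **indel event** is a maximal run of gap columns within one row keyed
  by its column span; identical spans in multiple rows (a deletion shared
  by a clade) count once. Event counting is the default because indel
  tools report events rather than gap columns; `mode="gap_columns"` is
  provided as the alternative convention. Whether sites with gaps should
  be excluded before SNP counting differs between tools; the rule here is
  documented behaviour, not an inference about any particular program.

## Synthetic data generator

The generator produces datasets with the statistical structure the
criteria are designed to detect — higher divergence between than within
species, with marker-to-marker rate variation:

* **Species tree:** pure-birth (Yule) topology, made ultrametric and
  rescaled so the root-to-tip height is `interspecific_depth / 2`
  (expected divergence of the deepest species pairs ≈ `interspecific_depth`).
  Because an unconstrained Yule tree can place its most recent split
  arbitrarily close to the present — shallower than the within-species
  depth, which would make a 100%-discrimination ground truth impossible by
  construction — terminal branches are extended so the shallowest split is
  at least `min_split_frac` (default 0.2) of the tree height before the
  present. Set `min_split_frac=0` for the raw Yule process.
* **Individuals:** each species tip carries a star of 2–5 individuals
  (uniformly drawn) at depth `intraspecific_depth / 2`, so two conspecific
  individuals diverge by `intraspecific_depth` in expectation. A star, not
  a coalescent: it is the simplest process satisfying "between > within"
  exactly; coalescent within-species genealogies are future work.
* **Sequences:** sites evolve independently down the tree under the K2P
  transition-probability matrix with transition/transversion rate ratio
  `kappa` (default 2.0) and equal base frequencies — matching the
  assumptions of the distance model being tested. Branch lengths are
  expected substitutions per site, multiplied by each marker's relative
  rate.
* **Markers (defaults):** lengths 497/636/366/346 bp with relative rates
  0.09/0.18/0.57/1.0 and 0/1/44/21 indel events — a slow *rbcL*-like
  locus through a fast ITS-like spacer, mirroring the rate ladder and
  indel richness observed in published four-marker plant-barcoding tables.
  Default depths are `interspecific_depth=0.05`, `intraspecific_depth=0.002`
  (a clear-gap scenario).
* **Indels:** inserted post hoc as gap spans shared by all individuals of
  a randomly chosen species. Spans are placed non-overlapping and
  non-adjacent by a composition construction (no rejection sampling), so
  the recovered event count equals the configured truth exactly.

What the generator does **not** emulate: hybridisation/introgression,
incomplete lineage sorting, ITS concerted-evolution dynamics, alignment
error, or rate variation among sites. Passing tests on synthetic data
therefore demonstrate the *machinery* is correct under the stated model,
not that any particular empirical marker set will reach the same rates.

All randomness derives from one seed through a fixed spawn order of
independent streams (tree, sampling depths, one sequence + one indel
stream per marker); identical configurations write byte-identical files.

## Pipeline conventions

* Multi-locus units use **strict intersection concatenation**: only samples
  present in every member marker are kept (no missing-data padding), so
  each unit has its own sample and species counts and rates are reported
  against their own denominators.
* Summary divergences, gap histograms and trees use K2P; the gap criterion
  uses p-distance by default. Both are configurable.
* Per-unit bootstrap seeds are derived as `(run seed, CRC32(unit label))`,
  so results are independent of grid order and reproducible per unit.
* Section-level evaluation reuses the same two criteria with section labels
  as groups; it is skipped (with a log note) when section labels are
  absent or incomplete, since monophyly of a partial leaf set is
  ill-defined against an unlabelled remainder.
* Percentages are reported to 2 decimals, distances to 4 decimals;
  comparisons themselves always use full precision.

## Problem sizes used in the shipped analyses

The bundled end-to-end analysis (`scripts/acceptance.py`) simulates the
default study — 21 species, 2–5 individuals each (69 individuals at the
default seed), four markers — and evaluates the four single markers and
all eight classical combinations with 1000 bootstrap replicates per tree.
Unit tests use smaller grids (4–10 species, 20–100 replicates) chosen to
keep the full suite fast while still exercising every code path; the
Monte-Carlo calibration checks use 50–100 kb two-taxon alignments, where
the K2P standard error is ~1e-3.

## Known limitations

* NJ is O(n³) with dense matrices; adequate for hundreds of taxa, not
  thousands.
* Undefined distances abort tree building for a unit rather than dropping
  the offending samples automatically; the report marks the unit failed
  with the reason.
* The gap criterion's `zero_intra` policy and the `complete` deletion mode
  are provided for cross-tool comparisons but are not the defaults, and
  combining them with saturated markers can exclude many pairs.
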