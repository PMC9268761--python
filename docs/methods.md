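# Methods

This note records the statistical conventions, the synthetic-data model and
the design decisions behind markerdiv, in the order data flows through the
pipeline.

## Band matrices and locus classification

The central object is a genotypes × loci binary matrix scored from
dominant-marker gels: entry 1 means the band was observed in that
genotype's lane. Dominant markers cannot distinguish heterozygotes from
dominant homozygotes, so presence/absence is all the information there is;
each locus is treated as independent. Invariants enforced on construction:
entries exactly 0/1, at least two genotypes, no all-zero locus column (a
band scored from a gel must have appeared in at least one lane — an
all-absent column indicates a scoring error, so it is rejected rather than
dropped), and a consistent primer → system mapping encoded in the locus id
(`SYSTEM:PRIMER:index`). Keeping the metadata inside the column label keeps
the interchange format to a single CSV.

Locus classes are exhaustive: *monomorphic* (sum = n), *unique* (sum = 1),
*polymorphic* otherwise, with unique counted as a subclass of polymorphic.
That containment is what makes the marginal arithmetic of a marker-survey
table close: monomorphic + polymorphic = total per primer.

### Percentage conventions

Published marker tables print per-primer polymorphism as a truncated
integer (2/3 → 66, 7/11 → 63), and the per-system "average polymorphism" as
the arithmetic mean of those printed values. markerdiv reproduces this
printing convention — it is the only convention consistent with the
five-genotype panel's published per-primer cells and system averages — but
always reports the raw percentage alongside, so nothing is lost to
truncation. The per-system display value is the mean rounded half-up to two
decimals. Note the convention means the displayed system average (e.g.
14.5) can differ from what further rounding to integer would print (15).

The fidelity index between systems A and B is
`round2(100·u_A/u_B) − round2(100·l_A/l_B)`; both ratios are computed in
decimal arithmetic and rounded half-up to two decimals *before* the
subtraction, matching how the intermediate terms are conventionally printed
(80.00 − 39.47 = 40.53). A reference system with zero unique bands makes
the index undefined and raises, rather than returning an infinity.

## Similarity coefficients

For each genotype pair, with `a` joint presences, `b`/`c` exclusive
presences and `d` joint absences over all scored loci:
Dice `2a/(2a+b+c)` (default — the standard choice for dominant markers,
since joint absence of an anonymous band is weak evidence of similarity),
Jaccard `a/(a+b+c)`, simple matching `(a+d)/(a+b+c+d)`. Monomorphic loci
are retained: they contribute shared presences and raise all pairwise
similarities, which matches how such matrices are conventionally analysed
(all scored loci enter the coefficient). A genotype with no bands at all
has an undefined coefficient and is reported by name. Distance for
clustering is the complement `1 − S`; the transform is monotone, which is
all a rank-driven agglomeration needs.

## WPGMA clustering

WPGMA merges the closest pair of clusters at height `d/2` and replaces
distances by the *simple* mean `d(i∪j,k) = (d(i,k)+d(j,k))/2`, i.e.
independent of cluster sizes (the "weighted" in the name refers to the
resulting down-weighting of earlier members). UPGMA (size-weighted mean) is
provided as an option. Both updates are reducible, so merge heights are
non-decreasing and the tree is a genuine ultrametric: cophenetic distance =
2 × LCA height = the merge distance at which two leaves first meet.

Numerical choices:

* **Tie-breaking.** When several pairs attain the minimal distance, the
  pair whose clusters have the lexicographically smallest contained leaf
  labels merges first (smaller label, then partner's). This makes output a
  pure function of the input matrix, independent of row order; it is a
  documented convention, not a claim about what any particular legacy
  package does internally.
* **Heights.** Node height = merge distance / 2, so leaf-to-leaf path
  length through the tree equals the merge distance. Newick branch lengths
  are parent height − child height.
* **Cutting.** `cut_tree(t, k)` removes the k−1 merges of greatest height
  (ties: later merges removed first). With monotone heights this equals
  keeping the first n−k merges. Memberships, not cut heights, are the
  output, since that is what diversity studies report.

## Morphological statistics

Traits are measured on replicates (default fixture: 10 plants per
genotype; flower-level traits are analysed as per-plant means of 50 flowers
each, so the error unit is the plant in both cases — the more conservative
of the two plausible choices, since treating 250 individual flowers as
independent replicates would overstate the degrees of freedom).

Per trait: one-way ANOVA with genotype as the factor; MSE pooled over
groups; F = MSB/MSE with p from the F distribution. Degenerate inputs are
defined, not errors: zero within-group variance with equal means → F is
NaN, p = 1, one letter for everyone; zero variance with distinct means →
F = ∞, p = 0, every differing pair significant.

Fisher's (unprotected) LSD declares a pair different at level α when the
mean gap exceeds `t(1−α/2, df_within)·sqrt(MSE·(1/n_i+1/n_j))`. The
unprotected version with the pooled error term is what a per-trait letter
display encodes; a Welch pairwise-t alternative is provided for
sensitivity. α defaults to 0.05; values above 0.5 are accepted but flagged
as degenerate. Being unprotected, the familywise error under the complete
null exceeds α (empirically ≈ 0.2–0.3 for 5 groups of 10); the test suite
records this, it is not a defect.

**Compact letter display.** Letters are the maximal cliques of the
non-significance graph (found via networkx), assigned a, b, c, … in order
of each clique's first genotype in table order. Two genotypes share a
letter *iff* they are not significantly different — exact by construction,
since every non-significant pair lies in some maximal clique and every
clique is a set of mutually non-significant genotypes. Letter order follows
the table's genotype order rather than descending means; this keeps the
display stable under re-analysis of the same table.

**Trait distance.** Genotype profiles of per-trait means are z-scored
across genotypes (sample sd, ddof = 1) before Euclidean distance, because
the traits span centimetres, millimetres and counts up to ~320 — without
standardization flower number would dominate the dendrogram entirely.
Constant traits carry no information after scaling and are dropped with a
warning. Standardized distance is invariant to affine changes of any
trait's units.

## Synthetic-data generator

The generator is the package's stand-in for unpublished gel scores and
greenhouse measurements; what it does and does not emulate bounds what the
tests can show.

**Band matrices.** A spec lists, per primer block, the counts of
monomorphic / polymorphic / unique loci. The generator emits exactly
`n_monomorphic` all-ones columns, `n_unique` single-one columns (owner
uniform unless pinned), and the remaining polymorphic columns with presence
counts drawn uniformly on [2, n−1] and uniformly random carrier sets
(unless pinned), then shuffles column order within the block. Class counts
are therefore *exact* by construction — the round-trip through the
classifier is the generator's key tested property — while the
band-frequency spectrum is uniform because no spectrum is published;
both the owners and the carrier sets can be pinned explicitly to plant
cluster structure. Feasibility is validated up front (e.g. non-unique
polymorphic columns need ≥ 3 genotypes) with the violated constraint named.

**The panel fixture** reproduces the published per-primer locus counts of
the five-genotype kalanchoe panel (12 primer blocks; 70 loci; 35/35
monomorphic/polymorphic; 9 unique; per-system totals 15/17/38). Because
only counts — not which genotype carries which band — are published, the
fixture's similarity values and tree are self-consistent simulation
outputs, not reconstructions of the original study's figures. Likewise the
morphology fixture anchors the five published trait maxima (yellow 40 cm
height; orange 9 inflorescences, 321 flowers, 2.1 cm flower length; violet
40 petals) and fills every other mean and all standard deviations with
documented synthetic values shaped to the panel's reported significance
pattern; replicate noise is i.i.d. Gaussian, which a mean ± SE report
cannot distinguish from any other second-moment-matched model.

**Planted partitions.** For cluster-recovery evaluation, a spec with one
outlier genotype (6 private bands), two tight pairs (10 pair-exclusive
bands each), 5 shared monomorphic bands and 8 uniform-random noise columns.
These sizes were chosen once as a realistic "well-separated panel" regime:
within-pair Dice similarity is dominated by core + pair bands, the outlier
shares only core + noise with everyone. Dice + WPGMA + cut(k=3) recovers
the planted partition in ≈100% of seeds at these settings; the acceptance
suite requires ≥ 95/100.

**Determinism.** All randomness flows through
`numpy.random.default_rng(seed)` carried in the spec; identical spec + seed
gives byte-identical CSV output, and the CLI threads one seed through a
whole run.

## Problem sizes

The package's native scale is small (a handful of genotypes, tens of
loci), and the test suite mirrors it: oracle comparisons use 200 random
matrices of ≤ 6 taxa / ≤ 20 loci, letter-display reconstruction 500 random
significance graphs, generator round-trips 500 random specs, recovery 100
seeds, and the null-simulation of the LSD familywise rate 400 replicates of
5 × 10 observations. These sizes give the properties involved no room to
hide (exhaustive per-pair tallies, exact count equalities) while keeping
the whole suite in seconds.

## Known limitations

* Band scoring itself (gel image → 0/1 calls) is out of scope; the matrix
  is the input.
* The Dice/WPGMA pipeline reproduces the *method* of the motivating study;
  its exact similarity values and dendrograms are unrecoverable without
  the unpublished band matrix, and no claim is made to reproduce them.
* The fidelity index is asymmetric and undefined when the reference system
  has no unique bands; interpret it as a relative yield contrast, not a
  distance.
* Unprotected LSD makes no multiplicity correction across pairs or traits.
* The generator draws loci independently; real multi-locus profiles can be
  correlated through shared fragments, and nothing in the tests probes
  linkage between loci.
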