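# markerdiv

Genetic-diversity analysis for **dominant molecular markers** (RAPD, ISSR,
SCoT): the kind of study where a panel of genotypes is fingerprinted by
PCR with arbitrary or semi-arbitrary primers, gels are scored into a binary
band-presence matrix, and diversity is summarized by polymorphism counts,
pairwise similarity and an ultrametric dendrogram — alongside a classical
morphological characterization with ANOVA and Fisher's LSD.

The package was built around a five-genotype ornamental-kalanchoe panel
(flower colours red, yellow, purple, orange, violet; 4 informative primers
per marker system, 70 scored loci) and ships a synthetic-data generator that
emulates such gel-scored matrices exactly, so the whole pipeline is testable
without any lab data.

## What it computes

**Marker arm.** Every locus column of a genotype × locus 0/1 matrix is
classified as *monomorphic* (band in all genotypes), *polymorphic* (in some
but not all) or *unique* (in exactly one; counted inside polymorphic).
Per primer: polymorphism % = 100 · polymorphic / total (printed floored, as
marker-survey tables do). Per system: totals, per-primer averages, and the
percentage **fidelity** of system A vs B,

```
fidelity = round2(100 · u_A / u_B) − round2(100 · l_A / l_B)
```

with `u` the unique-locus and `l` the total-locus counts.

**Similarity & clustering.** Pairwise genotype similarity from band sharing
— Dice `2a/(2a+b+c)` (the default; ignores joint absences), Jaccard
`a/(a+b+c)`, simple matching `(a+d)/n` — complemented to a distance
`D = 1 − S` and clustered by **WPGMA**: merge the closest pair at height
`d/2`, update `d(i∪j, k) = (d(i,k)+d(j,k))/2`. The result is an ultrametric
dendrogram (Newick export, cophenetic distances, k-cluster extraction);
UPGMA is available as an option.

**Morphological arm.** Replicate-level trait tables (plant height, numbers
of inflorescences/flowers/petals, flower length/diameter) are summarized as
mean ± SE, tested per trait by one-way ANOVA, and compared pairwise with
Fisher's LSD: significant iff
`|mean_i − mean_j| > t(1−α/2, df_within) · sqrt(MSE·(1/n_i + 1/n_j))`.
Outcomes are reported as a compact letter display (genotypes sharing a
letter are not significantly different), and genotypes are clustered on
z-scored trait-mean profiles.

## Worked example

```sh
markerdiv simulate --fixture --seed 1 --out panel
markerdiv markers --in panel/bands.csv --out panel
```

prints the per-primer report; the RAPD block and fidelity line read

```
RAPD	OPA2	2	1	1	0	50%
RAPD	OPA7	8	2	6	2	75%
RAPD	OPA9	3	1	2	2	66%
RAPD	OPA10	2	1	1	0	50%
RAPD	Average	3.75	1.25	2.5	1	60.25%
RAPD	Total	15	5	10	4
...
all	Total	70	35	35	9
fidelity	RAPD/SCoT	80.00	39.47			40.53%
```

i.e. 15 RAPD loci (10 polymorphic, 4 unique), an average RAPD polymorphism
of 60.25%, 70 loci overall with 35 polymorphic and 9 unique, and a
RAPD-vs-SCoT fidelity of 80.00 − 39.47 = 40.53%. Then

```sh
markerdiv cluster --in panel/bands.csv --out panel --k 3
markerdiv morpho  --in panel/traits.csv --out panel
```

write the Dice matrix, the WPGMA tree in Newick, a 3-cluster membership
table, and the per-trait LSD report with letters, e.g.

```
n_petals  F=882.4  LSD=1.362  violet=39.7a  red=6.8b  yellow=8.9c  purple=7.9bc  orange=8.3c
```

meaning violet's petal number (mean 39.7) is significantly different from
every other genotype at p ≤ 0.05, which share letters among themselves.

The same analyses are available from Python — see `examples/` for one
short script per capability (marker statistics, similarity + clustering,
morphology + LSD, custom simulations with planted cluster structure).

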