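"""Dice similarity and WPGMA dendrogram of the five genotypes.

Computes the genotype x genotype Dice matrix from band sharing, converts
it to a distance (1 - S), clusters with WPGMA and cuts the tree into
k = 3 groups.
"""

import numpy as np

from markerdiv import (
    cut_tree,
    dice_similarity,
    generate_band_matrix,
    kalanchoe_fixture,
    to_distance,
    wpgma,
)

band_spec, _ = kalanchoe_fixture(seed=1)
matrix = generate_band_matrix(band_spec)

sim = dice_similarity(matrix)
print("Dice similarity (1.0 = identical band profiles):")
with np.printoptions(precision=3):
    print(sim.genotype_ids)
    print(sim.values)

tree = wpgma(to_distance(sim))
print("\nWPGMA dendrogram (branch lengths in distance units / 2):")
print(tree.to_newick())

cut = cut_tree(tree, k=3)
print("\nk = 3 cluster membership (which genotypes group together):")
for i, members in enumerate(cut.clusters(), start=1):
    print(f"  cluster {i}: {sorted(members)}")
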