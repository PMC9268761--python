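"""Morphological arm: trait means +/- SE, Fisher's LSD letters, trait tree.

Simulates replicate-level measurements of the six panel traits, runs a
one-way ANOVA + LSD per trait, prints compact letter displays (genotypes
sharing a letter are not significantly different at p <= 0.05) and
clusters genotypes on their z-scored trait profiles.
"""

from markerdiv import (
    generate_trait_table,
    kalanchoe_fixture,
    lsd_test,
    morpho_distance,
    summarize,
    wpgma,
)

_, morpho_spec = kalanchoe_fixture(seed=1)
traits = generate_trait_table(morpho_spec)
summary = summarize(traits)

for trait in traits.traits:
    res = lsd_test(traits, trait, alpha=0.05)
    parts = ", ".join(
        f"{g}={res.means[g]:.1f}{res.letters[g]}" for g in res.genotypes
    )
    print(f"{trait:20s} F={res.f_stat:8.1f}  LSD={res.lsd_value:.3f}  {parts}")

# The trait dendrogram: Euclidean distance over z-scored trait means.
tree = wpgma(morpho_distance(summary, standardize=True))
print("\nmorphology dendrogram:", tree.to_newick())
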