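"""Build the six-dimensional odorant space and analyze its geometry.

Embeds every odorant as its vector of responses across the six sensillum
types, then prints the closest and farthest odorant pairs by Euclidean
distance (spikes/s), the first merges of the between-group-linkage
cluster tree, and the variance captured by three principal components of
the correlation-matrix PCA.
"""

import cimexolf as co
from cimexolf.presets import build_profiles

profiles, classes = build_profiles()
matrix, _ = co.gen_response_matrix(profiles, classes, n_replicates=6, seed=7)
space = co.build_space(matrix)
print(f"odorant space: {space.n_odorants} odorants, {space.n_pairs} pairs")

print("\ntop 5 closest pairs (weak responders are nearly indistinguishable):")
print(co.rank_pairs(space, 5, "closest")[
    ["odorant_a", "odorant_b", "distance"]
].to_string(index=False))

print("\ntop 5 farthest pairs (nonanal dominates the space):")
print(co.rank_pairs(space, 5, "farthest")[
    ["odorant_a", "odorant_b", "distance"]
].to_string(index=False))

tree = co.hcluster(space)
first = tree.linkage[0]
a, b = (tree.labels[int(i)] for i in first[:2])
print(f"\nfirst cluster merge: {a} + {b} at distance {first[2]:.2f}")

pca = co.pca_space(matrix, n_components=3)
print(
    "PCA: 3 components capture "
    f"{100 * pca.cumulative_variance:.2f}% of the variance "
    f"(per component: {(100 * pca.variance_explained[:3]).round(1)})"
)
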