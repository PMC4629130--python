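"""Run the full replicate screen and summarize tuning.

Simulates the 104-odorant x 6-sensillum screen (6 replicates per cell),
then prints the response-band distribution, the per-class excitatory
biases, and each sensillum's tuning-curve K value.  High K = narrowly
tuned (the amine-specialist C sensillum), low K = broadly tuned (Dβ).
"""

import cimexolf as co
from cimexolf.presets import build_profiles

profiles, classes = build_profiles()
matrix, records = co.gen_response_matrix(
    profiles, classes, n_replicates=6, seed=7
)
print(f"{matrix.n_cells} odorant-sensillum combinations "
      f"({len(matrix.odorants)} odorants x {len(matrix.sensilla)} sensilla)")

print("\nresponse bands (spikes/s):")
print(co.band_distribution(matrix))

bias = co.class_bias(matrix, threshold=50.0, mode="max").round(0)
print("\n% of class with an excitatory response (>=50 spikes/s):")
for cls in ("aldehyde", "alcohol", "aromatic", "heterocyclic",
            "carboxylic_acid", "amine"):
    print(f"  {cls:16s} {bias[cls]:5.0f}%")

print("\ntuning-curve K values (high = narrow):")
for s in matrix.sensilla:
    curve = co.tuning_curve(matrix, s)
    center = curve.odorant_order[len(curve.odorant_order) // 2]
    print(f"  {s:3s} K = {curve.k:5.1f}   strongest odorant: {center}")
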