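"""Phylogenetic path analysis over the 14-model registry.

Simulates traits from the 'direct4' causal structure (genome size directly
affects cell volume and doubling time; temperature affects genome size and
doubling time; GC content feeds genome size), evaluates all 14 candidate
models by Fisher's C / CICc, and prints the ranking plus the full
model-averaged path coefficients.
"""

from nucleotype.pathanalysis import model_registry, results_table, run_path_analysis
from nucleotype.simulate import sim_traits_dag, sim_tree

COEFS = {("GS", "CV"): 0.6, ("GS", "DT"): 0.5, ("TEMP", "GS"): -0.5,
         ("TEMP", "DT"): -0.5, ("GC", "GS"): 0.5}

tree = sim_tree(60, seed=5)
registry = model_registry()
direct4 = [m for m in registry if m.name == "direct4"][0]
data = sim_traits_dag(tree, direct4, COEFS, seed=5)

ranked, averaged = run_path_analysis(tree, data, registry)
print(results_table(ranked).round(3).to_string(index=False))
print("\nThe generating model (direct4) should rank near the top with "
      "delta-CICc < 2; models with p < 0.05 are rejected by the d-sep test.")

print("\nfull-average path coefficients (weights over all 14 models):")
print(averaged.to_frame().round(3).to_string(index=False))
print("\nEdges of the generating model should carry coefficients near "
      "their true standardized values, shrunk by averaging over models "
      "that omit them.")
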