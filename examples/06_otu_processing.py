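"""From a long OTU count table to a species-level abundance table.

Shows the observational pipeline: per-sample proportions, aggregation of
OTUs to species (unassigned OTUs dropped), and the >= 10-sample prevalence
filter that keeps only species seen often enough to model.
"""

import pandas as pd

from nucleotype.abundance import aggregate_species, counts_to_relative, filter_prevalence

otus = pd.DataFrame(
    {
        "otu_id":    ["o1", "o2", "o3", "o4"] * 12,
        "sample_id": [f"st{i}" for i in range(12) for _ in range(4)],
        "count":     ([8, 2, 5, 5] * 6) + ([0, 2, 5, 13] * 6),
        "species":   ["Thalassiosira_A", "Thalassiosira_A",
                      "Skeletonema_B", None] * 12,
    }
)

rel = counts_to_relative(otus)
print("per-sample proportions (first sample):")
print(rel[rel.sample_id == "st0"][["otu_id", "count", "proportion"]]
      .to_string(index=False))

agg = aggregate_species(rel)
print("\nspecies-level relative abundances (o1+o2 summed; o4 unassigned, dropped):")
print(agg.head(4).to_string(index=False))

kept = filter_prevalence(agg, min_samples=10)
print(f"\nspecies before prevalence filter: {agg.species.nunique()}, "
      f"after (>= 10 samples): {kept.species.nunique()}")
print("Species present in fewer than 10 samples are excluded before the "
      "abundance model sees them.")
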