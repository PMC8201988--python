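"""Benchmark rankings with the ECDF/AUC statistic.

Plants differential signal only at enhancers (marker promoters stay at
baseline) and compares the network-propagated ranking against the
promoter-only baseline: only the network ranking can see the planted
genes, and a random gene set calibrates near AUC = 0.5.
"""

import numpy as np

from epirank import (
    SimulationConfig,
    compare_rankings,
    ecdf_curve,
    run_pipeline_on_dataset,
    simulate,
)

dataset = simulate(SimulationConfig(marker_mode="enhancer", seed=1))
result = run_pipeline_on_dataset(dataset)

rng = np.random.default_rng(0)
genes = [p.gene for p in dataset.promoters]
gene_sets = {
    "planted_markers": dataset.truth.marker_genes,
    "random_set": list(rng.choice(genes, size=20, replace=False)),
}

table = compare_rankings(result.ranking, result.promoter_ranking, gene_sets)
table = table.rename(columns={"auc_a": "network_auc", "auc_b": "promoter_auc"})
print(table.round(3).to_string(index=False))
print("\nthe planted markers are enriched only in the network ranking "
      "(their promoters carry no differential signal), while the random "
      "set sits near 0.5 in both lists")

curve = ecdf_curve(result.ranking, dataset.truth.marker_genes, "planted_markers")
k = int(0.1 * curve.n)
print(f"\nfraction of markers recovered in the top 10% of the list: "
      f"{curve.ecdf[k - 1]:.2f}")
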