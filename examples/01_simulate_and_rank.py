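"""Simulate a toy two-condition epigenome and rank genes.

Generates 200 genes with ~5 enhancers each on a 50-Mb toy chromosome,
plants a 4-fold differential shift at the promoters and enhancers of 20
marker genes, runs the full pipeline (signal summarization -> differential
PCA -> PageRank propagation), and prints the top-ranked genes.
"""

from epirank import SimulationConfig, run_pipeline_on_dataset, simulate, truth_eval

dataset = simulate(SimulationConfig(seed=1))
result = run_pipeline_on_dataset(dataset)

markers = set(dataset.truth.marker_genes)
print(f"{len(dataset.promoters)} genes, {len(result.pirs)} retained enhancers, "
      f"{len(result.edges)} enhancer->promoter edges")
print("\ntop 10 genes (marker genes starred):")
for rank, row in result.ranking.head(10).iterrows():
    star = "*" if row.gene in markers else " "
    print(f"  {rank:>3} {star} {row.gene}  meta-gene score {row.score:.5f}")

enrichment = truth_eval(result.ranking, dataset.truth)
print(f"\nplanted-marker AUC: {enrichment.auc:.3f}")
print("(1.0 would mean all 20 planted markers occupy the top ranks; "
      "0.5 would mean the ranking carries no signal)")
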