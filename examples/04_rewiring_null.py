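"""Test marker enrichment against a connectivity-matched null.

Some genes simply have many enhancers; could high ranks be a degree
artifact?  The null rewires the enhancer->promoter graph while keeping
every vertex's in/out-degree, re-propagates the scores, and recomputes
the marker AUC.  A real epigenetic signal at the true enhancers should
collapse under rewiring.
"""

from epirank import SimulationConfig, rewiring_null, run_pipeline_on_dataset, simulate

dataset = simulate(SimulationConfig(seed=1))
result = run_pipeline_on_dataset(dataset)

null = rewiring_null(
    result.graph, dataset.truth.marker_genes, n_perm=200, seed=7
)
print(f"observed marker AUC:        {null.observed_auc:.4f}")
print(f"mean AUC after rewiring:    {null.null_aucs.mean():.4f}")
print(f"empirical p (add-one):      {null.empirical_p:.4g}")
print(f"relative AUC drop:          {100 * null.relative_drop:.1f}%")
print("\nrewiring scatters the enhancer contributions onto random "
      "promoters, so the marker enrichment drops: the observed ranks "
      "reflect where the differential signal sits, not how many "
      "enhancers a gene happens to have")
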