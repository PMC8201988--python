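# Methods

## Model and procedure

`epirank` ranks genes by the magnitude of epigenetic change between two
conditions, integrating multiple marks per element and multiple elements
per gene.

**Coordinates and elements.** All intervals are 0-based, half-open (BED
convention); strand is ignored. Promoters enter as point-like TSS
annotations and are extended to TSS ± `extension` (default 1000 bp),
anchoring on the record midpoint so that both 1-bp and interval promoter
inputs behave identically. PIRs (promoter-interacting regions) are kept
only when peaks of an enhancer-associated mark (H3K4me1 or H3K27ac by
default) overlap them by ≥ 1 bp in at least `min_peak_samples` (default
2) distinct samples, pooled over both conditions; samples are counted,
not peaks. Enhancer→promoter edges come either from interaction records
(an edge when one anchor overlaps an extended promoter and the other a
retained PIR, either orientation, ≥ 1 bp) or from nearest-TSS assignment
(one edge per PIR, measured from the PIR midpoint, ties to the lower
TSS).

**Signal.** Tracks are non-overlapping value blocks (bedGraph). Element
signal is the coverage-weighted sum Σ value × overlapped bases, which is
invariant to how a track splits constant coverage into blocks (a raw
block-value sum would not be). Values are length-normalized to
per-1-kb intensity (`scale=1000`; promoters are 2 kb after extension and
PIRs have variable length, so intensities become comparable; set
`scale=None` to disable), then x ↦ x^p with p = 0.5 (variance
stabilization for coverage-like data; the exponent is a parameter
because no canonical value exists), then quantile-normalized. Quantile
normalization runs within each mark across all samples of both
conditions jointly: normalizing conditions jointly preserves
between-condition differences, while normalizing across marks would
destroy mark-specific dynamic ranges. Ties map to the mean of the
reference values at the tied positions. Promoters and PIRs are
normalized as one element set per mark, since they feed a single
difference matrix.

**Differential PCA.** D[g, m] = mean_A − mean_B of normalized signal.
D = B V + E via SVD (no inferential layer: only coordinates and loadings
are used). No column centering by default — rows of D are already
differences and their magnitude is the signal; `center=True` is
available. Component signs are stabilized by making each loading row's
largest-magnitude entry positive; element scores Σ_{r≤k} |B_{gr}|
(k = `n_dpcs` = 2) are sign-agnostic regardless. Degenerate singular-value
ties admit any valid SVD; every downstream quantity used (absolute
coordinate sums, variance fractions) is tie-safe. An all-zero D yields a
defined result with zero scores and zero variance fractions (warned).

**Propagation.** The element graph is directed PIR → promoter with
vertex weights = element scores (promoters carry their own differential
weight too, so the meta-gene score blends promoter and enhancer
alterations). Personalized PageRank uses damping 0.85 (classical
default; `damping` is exposed), restart vector p(v) ∝ weight(v), and —
deliberately — dangling vertices (promoters, which have no out-edges)
redistribute their mass by p rather than uniformly, so the stationary
distribution is a function of element weights and wiring only.
Convergence: L1 change < 1e-12 (up to 10,000 iterations). The propagation
itself is delegated to networkx's PageRank (whose `dangling=None`
default implements exactly this policy); an independent dense power
iteration serves as the oracle in the tests. Genes with several
promoter records sum their promoters' PageRank (mass conservation at
gene level; `gene_aggregation="max"` is available). Ranking is by
descending score with lexicographic tie-breaks. The promoter-only
baseline ranks genes by the summed dPC scores of their promoter elements
alone.

A note on monotonicity: adding weight to one enhancer strictly improves
its target gene *relative to other genes*, but can lower every gene's
absolute PageRank share, because the enhancer vertex itself retains a
growing slice of the restart mass (on the 3-vertex chain the promoter
share is [1 + t(2α−1)] / [2(1 + αt)], decreasing in the enhancer's
restart probability t). Rank order, which is all the method uses, is
monotone; the property tests assert the relative version.

**Enrichment.** eCDF_G(k) = Σ_{i≤k} δ_i normalized by |G|; AUC is the
mean of the normalized step function over ranks (a Riemann/step rule,
not trapezoidal), which equals 1 + 1/N − mean_rank/N exactly — the tests
hold the two routes to 1e-12. Gene-set members missing from the ranked
universe are excluded from |G| (curated sets are usually larger than any
one universe) and logged. The rewiring null performs double-edge swaps —
pick (a→x), (b→y), replace with (a→y), (b→x) unless a duplicate arises —
10 × |edges| attempted swaps per replicate, preserving every in/out
degree exactly, then re-propagates and re-ranks; empirical p uses the
add-one correction (1 + #{null ≥ obs}) / (1 + n_perm).

## Synthetic data

The generator emulates a two-condition, multi-mark differential
epigenome study at desk scale. Defaults (also the conditions used by the
acceptance checks): 200 genes on a 50-Mb chromosome, PIR count per gene
~ Poisson(5) placed within ±1 Mb of the TSS (real promoter-interaction
networks average ~21 fragments per promoter; 5 keeps desk-scale runs
fast while preserving the network structure), 10% marker genes,
marker_mode "both" (promoter + enhancers planted), effect size 4,
3 samples per condition, six marks (H3K27ac, H3K4me1, H3K4me3, H3K36me3
activating; H3K27me3, H3K9me3 repressive).

Baseline intensity is lognormal: each element–mark pair draws a latent
mean `base_level`·exp(N(0, element_sigma)) (10 and 0.5 by default)
shared across samples, and each sample observation multiplies it by
exp(N(0, `noise_sigma`)) with sigma 0.3. Lognormal noise was chosen over
a count model because the pipeline consumes continuous block values;
effects are multiplicative (fold-change-like) and applied pre-transform
so the power transform acts as it would on real data: at planted
elements, activating marks are multiplied by the effect size in
condition A and repressive marks divided by it. Peaks are thresholded at
each track's median over elements rather than called — the support
filter, not peak calling, is what the pipeline exercises.

What the generator does **not** emulate: nucleosome-scale signal shape
within elements (blocks are flat per element), read-level sampling
noise, batch or replicate structure, background signal outside
regulatory elements, shared enhancers between genes (each PIR is wired
to one gene; shared targeting arises only through nearest-TSS linkage),
and copy-number or mappability artifacts. Passing recovery tests on
these data therefore shows the pipeline's statistical machinery is
correct and sensitive under clean planted signal — not that real tumor
epigenomes will yield AUCs of comparable size.

## Numerical choices and degenerate inputs

- Quantile normalization with a single sample column returns the input
  unchanged with a warning; its tie rule averages reference values.
- `dpca` rejects non-finite input; all-zero D is well-defined (above).
- PageRank with all-zero weights falls back to uniform personalization
  (warned); damping outside (0,1) is an error.
- Rewiring on graphs with < 2 edges returns the graph unchanged
  (warned); the same seed always yields the same rewired graph.
- Gene ranking ties break lexicographically, making every ranking
  deterministic.
- Empty BED files produce empty collections with a warning; malformed
  lines raise errors naming the line number.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
default 200-gene configuration (single replicates and 20-replicate
sweeps), 200 rewiring permutations for the null, 500 random gene sets
over a 1,000-gene ranking for AUC calibration, 100 random matrices for
the decomposition oracle, and all ≤ 6-vertex graphs (with sampled edge
subsets where the enumeration exceeds 64) for the propagation oracle.
These sizes were chosen so a complete run takes well under a minute on
one core while keeping Monte-Carlo standard errors small relative to the
tolerances tested.

## Known limitations

- Two conditions only; no replicate-aware variance modeling beyond
  condition means (heterogeneous groups inflate within-group variance
  and dilute D).
- Vertices are weighted, edges are not: interaction frequency or
  contact strength is not modeled.
- BigWig tracks are consumed via their bedGraph equivalent (the block
  model is identical); no liftover, no strand-aware TSS logic.
- The inferential machinery of the original differential-PCA literature
  (component significance, locus-level FDR) is intentionally absent:
  the ranking uses only the coordinates.
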