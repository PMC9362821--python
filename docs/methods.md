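# Methods

## Synthetic droplet cohorts

The generator (`nbtme.simdata`) draws UMI counts from a negative-binomial
law parameterized by mean and a single global dispersion θ
(variance = μ + μ²/θ, sampled as a gamma–Poisson mixture):

```
count[g, c] ~ NB(mean = baseline(g) · fold(g, pop(c)) · lib(c),  dispersion = θ)
```

- `baseline(g) ~ Gamma(shape, scale)` — per-gene baseline mean in counts per
  cell. Defaults `shape = 0.5`, `scale = 1.0` give a typical droplet profile
  (many weakly expressed genes, cell depth ≈ 1,000 counts for a 2,000-gene
  universe).
- `fold(g, pop)` — a population's marker genes have their mean multiplied by
  the program fold change (default 6 for canonical cell-type programs;
  benchmark presets use 4). Per-gene overrides allow "intermediate" markers
  (CD14 at fold 2 on non-classical monocytes) and strongly expressed
  subset-defining genes (the macrophage-subset and MDSC short-signature
  genes at fold 12 — such genes are chosen as subset markers in real data
  precisely because they are highly expressed).
- `lib(c) ~ LogNormal(0, 0.3)` — per-cell library-size factor.
- `θ = 2` — moderate over-dispersion, a realistic droplet value; the
  downstream statistics are rank-based and insensitive to its exact value.
- Marker genes have their baseline floored at `marker_baseline_min = 0.25`
  counts/cell: a canonical marker is by definition detectably expressed; the
  unconditional gamma law would otherwise leave some planted markers at
  ~10⁻³ counts, unrecoverable by any method.

Cell labels are drawn per sample from the configured composition vector
(multinomially, or exactly in benchmark presets). Orthology is simulated
explicitly: a configurable number of one-to-one pairs, multi-mapped genes
(one species-A gene to ≥ 2 species-B genes, which the one-to-one filter must
remove) and unmapped genes per species. Cognate population pairs share their
program through the one-to-one table. No doublets, ambient RNA, batch
effects or UMI chemistry are simulated — multi-sample integration is out of
scope, so each species behaves as a single batch.

The full paired preset (`presets.mouse_human_cohort`) emulates the study
design the package targets: 3 mouse tumours × 1,900 cells and 10 human
biopsies × 400 cells, eleven populations per species (tumour,
Pecam1⁺/Ccr2⁺/Apoe⁺ macrophages, MDSCs, T/B/NK cells, DCs, CAFs,
endothelium, with the mouse macrophage subsets cognate to human
non-classical monocytes / monocytes / macrophages), canonical marker symbols
aliased onto orthologue slots so the bundled registries and signature
fixtures apply verbatim, and planted composition shifts: MDSC proportion
0.05 at diagnosis vs 0.15 at relapse, extra non-classical monocytes in
MYCN-amplified biopsies (5/5 amplified, 5/5 diagnosis/relapse, the two
factors not confounded). Per-population cell counts for the human cohort are
free parameters of the design and were fixed once at the values above.

In the cross-species benchmark preset (`presets.xspecies_benchmark`, 6
shared + 2 species-specific populations, fold 4, 150 cells/population),
species-specific populations are modelled as *related variants* of shared
cell types: half of each program overlaps a shared program of its own
species (a different one per population and per species), half comes from
unmapped genes. A population whose markers were entirely unmapped would have
a flat profile on the orthologue panel, and two such flat rows (one per
species) trivially match each other; a related variant instead resembles an
existing type without having any cognate, which is also the biologically
typical situation.

## What passing tests do and do not show

The generator's populations are discrete, programs are mostly disjoint, and
there is no batch structure, so recovery rates measured here are upper
bounds on real-data behaviour. What the tests *do* establish is the
correctness of the statistics (against exact enumeration and brute-force
oracles) and that the cross-species procedure recovers planted
correspondence under realistic count noise at the stated effect sizes.

## Statistics

**Markers.** Cluster-vs-rest two-sided Wilcoxon rank-sum on log-normalized
values: exact enumeration of the rank-sum distribution (midranks for ties,
doubled smaller tail) when both groups have ≤ 8 cells, otherwise the
tie-corrected normal approximation with continuity correction. Genes are
prefiltered on |log2 fold change| ≥ 0.25 and detection fraction ≥ 0.1 on
either side, with `lfc = log2((mean expm1 in + 1)/(mean expm1 rest + 1))`
(pseudo-counted, bounded). BH correction is applied within each cluster.
"Top-k" keeps upregulated genes with q < 0.05 ordered by ascending p, then
descending lfc, then gene id (a deterministic total order).

**Variable genes.** Dispersion = var/mean of the *de-logged* depth-normalized
expression, ties broken lexicographically. On that scale technical noise is
near-Poisson and the ratio is flat in the mean, so biological variation
stands out at any expression level; the same ratio computed on log values is
dominated by near-zero noise genes.

**Module scores.** All genes are ranked by average log-normalized expression
and cut into `n_bins = 25` equal-frequency bins; each signature gene
contributes `min(n_ctrl = 100, bin size)` control genes sampled without
replacement (seeded) from its bin; the score is the mean signature
expression minus the mean control expression per cell. The score is
invariant to adding a constant to the matrix and to cell order. Signature
genes missing from a matrix are dropped with a warning — the normal case for
cross-species application — and an optional case-folding layer matches
mouse/human symbol capitalization.

**Annotation.** Cluster means are z-scored per gene across clusters
(sample sd, zero variance → 0); a cell type's evidence is the mean of +z
over "high" markers, −z over "absent" markers and −|z| over "intermediate"
markers. Clusters are assigned the argmax type; a margin (best − second
best) below 0.05 yields "undefined". The default pipeline over-clusters
(Leiden, resolution 2.0) and annotates each sub-cluster, the standard
practice when cluster counts and population counts need not match.

**Cross-species correspondence.** Per-cluster means over the orthologue
panel are z-scored per gene *within each species* before stacking —
without this, species-level depth and scale differences dominate the first
dendrogram split. Rows (and, separately, columns) are clustered with
average linkage (UPGMA) on Pearson correlation distance (1 − r), the
standard choice for expression heatmaps; both metric and linkage are
arguments. The clustering itself uses only the panel genes. Cognate pairs
are scored by (a) mutual nearest cross-species neighbourhood in profile
distance and (b) whether their cophenetic join height is strictly below
either member's join with any row outside the pair.

**Composition.** Proportions are per sample (optionally excluding
tumour-labeled cells before normalizing, so the TME is compared on its
own). Group comparison is deliberately descriptive: difference of group
means with a seeded percentile bootstrap over samples, resampling within
each group, samples sorted by id so results are independent of row order.
With 5 samples per group a hypothesis test would overclaim; the package
reports an effect estimate and its resampling uncertainty.

## Numerical conventions

- Standardization uses sample sd (n − 1); zero-variance genes map to zeros;
  scaling clips at ±10 by default.
- Log-normalization uses scale factor 10,000 and natural log.
- HVG ties and top-k ties break lexicographically; agglomeration ties break
  at the lowest pair index (SciPy's deterministic order).
- Every stochastic step (simulation, control-gene sampling, clustering,
  bootstrap) takes an explicit seed; identical inputs give byte-identical
  outputs.
- Degenerate inputs: zero-total cells, empty cell subsets, clusters with no
  cells, all-missing signatures and NaN profiles raise informative errors;
  clusters with < 3 cells are skipped from marker testing with a warning.

## Known limitations

- The percentile bootstrap with 5 samples per group undercovers: the true
  coverage of the nominal 95% CI for the composition difference is ≈ 0.87
  (measured over 2,000 simulated cohorts) because the between-sample
  variance is estimated on ~8 degrees of freedom. This is a property of the
  estimator at this cohort size, not of the implementation; CI widths from
  such small cohorts should be read as slightly optimistic.
- Marker-gene programs are planted as independent genes; co-expression
  structure within programs is not simulated, which mainly affects how
  quickly module-score noise averages out.
- Benchmark problem sizes (1,000–2,000 genes, 150–200 cells per population,
  10–20 seeds) were chosen as the smallest designs at which the measured
  rates are stable; they are package defaults, not constants of the method.
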