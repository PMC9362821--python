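# nbtme

Cross-species single-cell analysis of the neuroblastoma tumour
microenvironment (TME).

Neuroblastoma, a paediatric cancer of the sympathetic nervous system, has an
immunosuppressive TME: few T cells (and those expressing inhibitory
receptors such as LAG3, TIGIT, CTLA4, HAVCR2 and PDCD1), several macrophage
subsets, myeloid-derived suppressor cells (MDSCs) and two
cancer-associated-fibroblast (CAF) populations. A central question for
anyone working with the MYCN-driven mouse model is whether the populations
seen in mouse tumours correspond to the populations found in patient
biopsies. `nbtme` packages the computational side of that comparison as a
tested, reusable pipeline for droplet scRNA-seq counts:

- **`nbtme.simdata` / `nbtme.presets`** — a seeded negative-binomial
  simulator of paired mouse/human droplet cohorts with planted cell
  populations, marker programs, a one-to-one/many-to-many orthologue table,
  clinical-group composition shifts (MYCN status, diagnosis vs relapse) and
  full ground truth, so every downstream stage is testable without any data
  download.
- **`nbtme.preprocess`** — log-normalization (`log(1 + c·s/total)`),
  dispersion-based gene selection, per-gene standardization, PCA + k-means
  or Leiden clustering, and cluster annotation against a registry of
  canonical markers (Cd3e, Cd68, Phox2b, S100A8, ...).
- **`nbtme.markers`** — cluster-vs-rest Wilcoxon rank-sum markers (exact
  enumeration for group sizes ≤ 8, tie-corrected normal approximation
  otherwise), Benjamini–Hochberg correction, and compact top-*k* "short
  signatures".
- **`nbtme.signatures`** — control-matched module scores: for each
  signature gene, control genes are sampled from the same
  average-expression bin, and `score = mean(signature) − mean(controls)`;
  plus signature-based splitting of sub-populations and inhibitory-receptor
  coverage.
- **`nbtme.xspecies`** — the cross-species correspondence procedure: top-50
  upregulated genes per cluster in both species, one-to-one orthologue
  filtering, the deduplicated union panel, per-species z-scored cluster
  profiles, UPGMA clustering under correlation distance (Newick export),
  mutual-nearest-neighbour reports for cognate populations, and projection
  of a signature from one species onto the other.
- **`nbtme.composition`** — per-sample cell-type proportions and
  descriptive group comparisons (difference of group means with a seeded
  percentile bootstrap CI — no p-values at n = 5 vs 5).

## Worked example

```python
import nbtme
from nbtme import presets

# paired benchmark: 6 shared + 2 species-specific populations, fold 4
config = presets.xspecies_benchmark(seed=5)
result = nbtme.simulate_tme(config)

lognorms, labels, top50 = {}, {}, {}
for sp in ("mouse", "human"):
    lognorms[sp] = nbtme.lognormalize(result.counts[sp])
    labels[sp] = nbtme.benchmarks.truth_clusters(result, sp)
    table = nbtme.rank_markers(lognorms[sp], labels[sp])
    top50[sp] = [nbtme.top_k_upregulated(table, c, k=50)
                 for c in sorted(set(table["cluster"]))]

panel = nbtme.build_union_geneset(top50["mouse"], top50["human"],
                                  result.truth.orthologues)
profile = nbtme.cluster_profile_matrix(
    lognorms["mouse"], labels["mouse"], lognorms["human"], labels["human"],
    panel, species=("mouse", "human"))
pairs = [(("mouse", a), ("human", b)) for a, b in result.truth.cognate_pairs]
print(len(panel))
print(nbtme.correspondence_score(profile, pairs))
```

prints the orthologue-pair panel size and the per-pair report:

```
170
                             distance  mutual_nearest  joined_first
pair
mouse:mdsc~human:mdsc        0.259901            True          True
mouse:shared1~human:shared1  0.234582            True          True
mouse:shared2~human:shared2  0.259176            True          True
mouse:shared3~human:shared3  0.258123            True          True
mouse:shared4~human:shared4  0.320286            True          True
mouse:shared5~human:shared5  0.311439            True          True
```

i.e. the union of per-cluster top-50 genes collapses to 170 one-to-one
orthologue pairs, and every cognate mouse/human population pair is mutually
nearest across species (correlation distance on the z-scored profiles) and
joins the dendrogram before any non-cognate row. The same objects feed
`hierarchical_correspondence(profile).to_newick()` for the joint
mouse+human dendrogram and `project_signature(...)` for scoring a
mouse-derived MDSC signature on the human cells.

A shell-level equivalent is available via the `nbtme` CLI
(`simulate`, `preprocess`, `markers`, `score`, `xspecies`, `composition`).

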