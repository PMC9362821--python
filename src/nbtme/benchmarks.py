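"""Ground-truth benchmarks that exercise the full pipeline on planted data.

Each function simulates a preset design, runs the relevant analysis exactly
as a user would, and measures performance against the generator's ground
truth: marker recovery and the matched-null false-positive rate, the
cross-species mutual-nearest-neighbour / dendrogram-adjacency rates for
cognate populations, cross-species signature projection AUC, signature-based
splitting accuracy, composition-shift recovery with bootstrap CIs, and
end-to-end annotation accuracy. They are deterministic given their seeds.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import presets
from .composition import cluster_proportions, compare_groups
from .markers import derive_short_signature, rank_markers, top_k_upregulated
from .preprocess import (
    ClusterLabels,
    annotate_clusters,
    cluster_cells,
    load_marker_registry,
    lognormalize,
    scale_genes,
    select_hvg,
)
from .signatures import split_by_signatures
from .simdata import SimResult, simulate_tme
from .xspecies import (
    build_union_geneset,
    cluster_profile_matrix,
    correspondence_score,
    project_signature,
)

__all__ = [
    "truth_clusters",
    "marker_recovery_benchmark",
    "null_fpr_benchmark",
    "xspecies_correspondence_benchmark",
    "projection_benchmark",
    "split_accuracy_benchmark",
    "composition_recovery_benchmark",
    "composition_coverage_benchmark",
    "annotation_accuracy_benchmark",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)]


def truth_clusters(result: SimResult, species: str) -> ClusterLabels:
    """Ground-truth population labels as contiguous cluster ids with names."""
    truth = result.truth.labels[species]
    cats = sorted(truth.unique())
    mapping = {c: i for i, c in enumerate(cats)}
    return ClusterLabels(
        pd.Series(truth.map(mapping).to_numpy(), index=truth.index, name="cluster"),
        names={i: c for c, i in mapping.items()},
    )


def marker_recovery_benchmark(
    seed: int = 0, fold_change: float = 4.0, **preset_kwargs
) -> dict:
    """Fraction of planted markers recovered at q < 0.05 in their population."""
    config = presets.marker_recovery(seed=seed, fold_change=fold_change, **preset_kwargs)
    result = simulate_tme(config)
    species = config.species_a.name
    lognorm = lognormalize(result.counts[species])
    labels = truth_clusters(result, species)
    table = rank_markers(lognorm, labels)
    hits = table[(table["qval"] < 0.05) & (table["lfc"] > 0)]
    recovered = {
        (row.cell_type, row.gene) for row in hits.itertuples()
    }
    planted = {
        (pop, gene)
        for pop, genes in result.truth.marker_sets[species].items()
        for gene in genes
    }
    rate = len(recovered & planted) / len(planted)
    return {"recovery_rate": rate, "n_planted": len(planted)}


def null_fpr_benchmark(seed: int = 0, alpha: float = 0.05, **preset_kwargs) -> dict:
    """Per-gene false-positive rate on the matched null (fold change 1)."""
    config = presets.marker_recovery(seed=seed, fold_change=1.0, **preset_kwargs)
    result = simulate_tme(config)
    species = config.species_a.name
    lognorm = lognormalize(result.counts[species])
    labels = truth_clusters(result, species)
    # no prefilters: every gene is tested in every cluster under the null
    table = rank_markers(lognorm, labels, min_frac=0.0, min_lfc=0.0)
    fpr = float((table["pval"] < alpha).mean())
    return {"fpr": fpr, "nominal": alpha, "n_tests": len(table)}


def _benchmark_pipeline(seed: int, top_k: int = 50, **preset_kwargs):
    config = presets.xspecies_benchmark(seed=seed, **preset_kwargs)
    result = simulate_tme(config)
    names = [d.name for d in config.designs]
    lognorms = {sp: lognormalize(result.counts[sp]) for sp in names}
    labels = {sp: truth_clusters(result, sp) for sp in names}
    tables = {}
    sets = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sp in names:
            tables[sp] = rank_markers(lognorms[sp], labels[sp])
            sets[sp] = [
                top_k_upregulated(tables[sp], c, k=top_k)
                for c in sorted(set(tables[sp]["cluster"]))
            ]
    return config, result, names, lognorms, labels, tables, sets


def xspecies_correspondence_benchmark(
    seeds: list[int] | int = 20, top_k: int = 50, **preset_kwargs
) -> dict:
    """Cognate-pair correspondence over simulation seeds.

    Reports the fraction of (seed x cognate pair) cases that are mutual
    nearest cross-species neighbours and that join in the dendrogram before
    any non-cognate row, and how often a species-specific population is a
    cross-species mutual nearest neighbour (expected: never).
    """
    if isinstance(seeds, int):
        seeds = _child_seeds(seed=20230, n=seeds)
    mnn, joined, specific_mnn, panel_sizes = [], [], [], []
    for seed in seeds:
        (config, result, names, lognorms, labels, _tables, sets) = _benchmark_pipeline(
            seed, top_k=top_k, **preset_kwargs
        )
        a, b = names
        panel = build_union_geneset(sets[a], sets[b], result.truth.orthologues)
        panel_sizes.append(len(panel))
        profile = cluster_profile_matrix(
            lognorms[a], labels[a], lognorms[b], labels[b], panel, species=(a, b)
        )
        pairs = [((a, pa), (b, pb)) for pa, pb in result.truth.cognate_pairs]
        report = correspondence_score(profile, pairs)
        mnn.extend(report["mutual_nearest"].tolist())
        joined.extend(report["joined_first"].tolist())

        # species-specific rows must not be cross-species mutual NNs
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(profile.to_numpy(), metric="correlation"))
        rows = list(profile.index)
        for i, (sp, name) in enumerate(rows):
            if "only" not in name:
                continue
            others = [j for j, r in enumerate(rows) if r[0] != sp]
            nearest = min(others, key=lambda j: (D[i, j], j))
            own = [j for j, r in enumerate(rows) if r[0] == sp]
            back = min(own, key=lambda j: (D[nearest, j], j))
            specific_mnn.append(back == i)
    return {
        "mnn_rate": float(np.mean(mnn)),
        "joined_first_rate": float(np.mean(joined)),
        "specific_mnn_count": int(np.sum(specific_mnn)),
        "n_cases": len(mnn),
        "mean_panel_size": float(np.mean(panel_sizes)),
    }


def projection_benchmark(
    seeds: list[int] | int = 10, k: int = 20, **preset_kwargs
) -> dict:
    """Mouse-derived MDSC top-k signature projected onto the human dataset.

    For each seed: derive the top-k upregulated genes of the mouse MDSC-like
    population, translate them through the one-to-one orthologue table,
    score the human cells, and record whether the planted human MDSC-like
    population has the top mean score plus the score-vs-truth AUC.
    """
    from sklearn.metrics import roc_auc_score

    if isinstance(seeds, int):
        seeds = _child_seeds(seed=20231, n=seeds)
    aucs, top_hits = [], []
    for seed in seeds:
        (config, result, names, lognorms, labels, tables, _sets) = _benchmark_pipeline(
            seed, **preset_kwargs
        )
        a, b = names
        mdsc_cluster = next(
            c for c, n in labels[a].names.items() if n == "mdsc"
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sig = derive_short_signature(
                tables[a], mdsc_cluster, k=k, cluster_names=labels[a].names
            )
            score, _report = project_signature(
                sig, result.truth.orthologues, lognorms[b], seed=seed
            )
        truth_b = result.truth.labels[b]
        means = score.scores.groupby(truth_b).mean()
        top_hits.append(means.idxmax() == "mdsc")
        aucs.append(
            roc_auc_score((truth_b == "mdsc").to_numpy(), score.scores.to_numpy())
        )
    return {
        "mean_auc": float(np.mean(aucs)),
        "min_auc": float(np.min(aucs)),
        "top_cluster_rate": float(np.mean(top_hits)),
        "n_seeds": len(seeds),
    }


def split_accuracy_benchmark(seed: int = 0, **preset_kwargs) -> dict:
    """Signature-based splitting of a planted two-program fibroblast mixture.

    The two planted marker programs play the role of the published subset
    signatures a user would supply; cells are assigned to whichever program
    scores higher (and positive).
    """
    from .signatures import GeneSet

    config = presets.caf_split_mixture(seed=seed, **preset_kwargs)
    result = simulate_tme(config)
    species = config.species_a.name
    lognorm = lognormalize(result.counts[species])
    programs = {p.name: p.marker_genes for p in config.species_a.populations}
    sig_d = GeneSet("dpvl_like", programs["caf_dpvl"])
    sig_i = GeneSet("impvl_like", programs["caf_impvl"])
    assigned = split_by_signatures(lognorm, lognorm.cells, sig_d, sig_i, seed=seed)
    truth = result.truth.labels[species].map(
        {"caf_dpvl": "dpvl_like", "caf_impvl": "impvl_like"}
    )
    accuracy = float((assigned == truth).mean())
    return {
        "accuracy": accuracy,
        "unassigned_rate": float((assigned == "unassigned").mean()),
    }


def _one_cohort_comparison(seed: int, n_boot: int, group_field: str = "timepoint"):
    config = presets.cohort_composition(seed=seed)
    result = simulate_tme(config)
    species = config.species_a.name
    props = cluster_proportions(
        result.truth.labels[species], result.truth.sample_of[species]
    )
    meta = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "mycn_status": s.mycn_status,
                "timepoint": s.timepoint,
            }
            for s in config.species_a.samples
        ]
    ).set_index("sample_id")
    return compare_groups(props, meta, group_field, n_boot=n_boot, seed=seed)


def composition_recovery_benchmark(
    n_cohorts: int = 50, seed: int = 0, n_boot: int = 500
) -> dict:
    """Recovery of the planted MDSC relapse enrichment over replicate cohorts.

    A cohort succeeds when the diagnosis-vs-relapse MDSC difference has the
    correct (positive, relapse-high) direction and its bootstrap CI excludes
    zero.
    """
    true_diff = (
        presets.MDSC_RELAPSE_PROPORTION
        - presets.human_sample_composition("non_amplified", "diagnosis")["mdsc"]
    )
    successes, diffs = [], []
    for s in _child_seeds(seed, n_cohorts):
        row = _one_cohort_comparison(s, n_boot).loc["mdsc"]
        successes.append(row["direction"] > 0 and row["ci_low"] > 0)
        diffs.append(row["difference"])
    return {
        "success_rate": float(np.mean(successes)),
        "mean_difference": float(np.mean(diffs)),
        "true_difference": float(true_diff),
        "n_cohorts": n_cohorts,
    }


def composition_coverage_benchmark(
    n_cohorts: int = 200, seed: int = 1, n_boot: int = 200
) -> dict:
    """Empirical coverage of the nominal 95% bootstrap CI for the MDSC shift."""
    true_diff = (
        presets.MDSC_RELAPSE_PROPORTION
        - presets.human_sample_composition("non_amplified", "diagnosis")["mdsc"]
    )
    covered = []
    for s in _child_seeds(seed, n_cohorts):
        row = _one_cohort_comparison(s, n_boot).loc["mdsc"]
        covered.append(row["ci_low"] <= true_diff <= row["ci_high"])
    return {
        "coverage": float(np.mean(covered)),
        "nominal": 0.95,
        "n_cohorts": n_cohorts,
    }


def annotation_accuracy_benchmark(
    seed: int = 0, species: str = "mouse", n_hvg: int = 1000,
    n_pcs: int = 20, resolution: float = 2.0, **preset_kwargs
) -> dict:
    """End-to-end cell typing on the full paired-cohort design.

    Simulate, normalize, select variable genes, scale, cluster (Leiden) and
    annotate against the bundled registry; report the fraction of cells
    whose assigned type equals their planted population.
    """
    config = presets.mouse_human_cohort(seed=seed, **preset_kwargs)
    result = simulate_tme(config)
    lognorm = lognormalize(result.counts[species])
    scaled = scale_genes(lognorm.subset_genes(select_hvg(lognorm, n_hvg)))
    labels = cluster_cells(scaled, n_pcs=n_pcs, resolution=resolution, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ann = annotate_clusters(lognorm, labels, load_marker_registry(species))
    named = labels.with_names(ann.cluster_types)
    accuracy = float((named.cell_types() == result.truth.labels[species]).mean())
    return {
        "accuracy": accuracy,
        "n_clusters": labels.n_clusters,
        "n_cells": lognorm.n_cells,
    }
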