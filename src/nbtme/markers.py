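"""Cluster-vs-rest differential markers and compact top-k signatures.

Each cluster is tested against all remaining cells with a two-sided
Wilcoxon rank-sum test on log-normalized expression: exact enumeration when
both groups have at most 8 cells, the tie-corrected normal approximation
otherwise. Genes are prefiltered on detection fraction and on the log2
fold-change

    lfc = log2((mean(expm1 expr in cluster) + 1) / (mean(expm1 expr in rest) + 1)),

i.e. a pseudo-counted ratio of de-logged means. P-values receive
Benjamini-Hochberg correction within each cluster. "Top-k upregulated"
lists and short signatures (default k = 20) feed both the per-population
detection signatures and the cross-species gene panel.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import LogNormMatrix
from .preprocess import ClusterLabels
from .signatures import GeneSet

__all__ = [
    "rank_markers",
    "top_k_upregulated",
    "derive_short_signature",
    "exact_ranksum_p",
]

MARKER_COLUMNS = [
    "cluster",
    "gene",
    "lfc",
    "frac_in",
    "frac_rest",
    "pval",
    "qval",
]


def exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Wilcoxon rank-sum p-value by full enumeration.

    Midranks handle ties; the two-sided p doubles the smaller tail
    probability of the observed rank sum (capped at 1), the convention of
    the exact Mann-Whitney test. Intended for group sizes <= 8.
    """
    n1, n = len(x), len(x) + len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n1].sum()
    sums = np.fromiter(
        (sum(combo) for combo in itertools.combinations(ranks, n1)),
        dtype=float,
        count=math.comb(n, n1),
    )
    eps = 1e-9
    lower = np.mean(sums <= w_obs + eps)
    upper = np.mean(sums >= w_obs - eps)
    return float(min(1.0, 2.0 * min(lower, upper)))


def _test_cluster(
    X_in: np.ndarray, X_rest: np.ndarray
) -> np.ndarray:
    """Rank-sum p-values for each gene (rows) of cluster vs rest."""
    n1, n2 = X_in.shape[1], X_rest.shape[1]
    if n1 <= 8 and n2 <= 8:
        return np.array(
            [exact_ranksum_p(X_in[g], X_rest[g]) for g in range(X_in.shape[0])]
        )
    res = stats.mannwhitneyu(
        X_in, X_rest, axis=1, alternative="two-sided", method="asymptotic"
    )
    return np.asarray(res.pvalue)


def rank_markers(
    lognorm: LogNormMatrix,
    labels: ClusterLabels,
    min_frac: float = 0.1,
    min_lfc: float = 0.25,
) -> pd.DataFrame:
    """Cluster-vs-rest marker table for every cluster.

    Genes are tested when |lfc| >= ``min_lfc`` and detected in at least
    ``min_frac`` of cells on either side. Clusters with fewer than 3 cells
    are skipped with a warning. Rows are sorted by
    (cluster, ascending p, descending lfc, gene id); the ``cell_type``
    column is filled when the labels carry cluster names.
    """
    if not 0 <= min_frac <= 1:
        raise ValueError("min_frac must be in [0, 1]")
    clusters = np.sort(labels.labels.unique())
    if len(clusters) < 2:
        raise ValueError("rank_markers requires at least 2 clusters")

    X = lognorm.values.to_numpy()
    genes = lognorm.genes
    expm1 = np.expm1(X)
    detected = X > 0
    total_expm1 = expm1.sum(axis=1)
    total_det = detected.sum(axis=1)
    n_cells = X.shape[1]
    label_arr = labels.labels.reindex(lognorm.cells).to_numpy()

    frames = []
    for c in clusters:
        in_mask = label_arr == c
        n1 = int(in_mask.sum())
        n2 = n_cells - n1
        if n1 < 3:
            warnings.warn(
                f"cluster {c} has {n1} cells (< 3) and was skipped", stacklevel=2
            )
            continue
        mean_in = expm1[:, in_mask].sum(axis=1) / n1
        mean_rest = (total_expm1 - mean_in * n1) / n2
        frac_in = detected[:, in_mask].sum(axis=1) / n1
        frac_rest = (total_det - frac_in * n1) / n2
        lfc = np.log2((mean_in + 1.0) / (mean_rest + 1.0))
        tested = (np.abs(lfc) >= min_lfc) & (
            (frac_in >= min_frac) | (frac_rest >= min_frac)
        )
        if not tested.any():
            continue
        pvals = _test_cluster(X[tested][:, in_mask], X[tested][:, ~in_mask])
        qvals = multipletests(pvals, method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "cluster": c,
                    "gene": genes[tested],
                    "lfc": lfc[tested],
                    "frac_in": frac_in[tested],
                    "frac_rest": frac_rest[tested],
                    "pval": pvals,
                    "qval": qvals,
                }
            )
        )
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=MARKER_COLUMNS)
    table = table.sort_values(
        ["cluster", "pval", "lfc", "gene"],
        ascending=[True, True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    if labels.names is not None:
        table["cell_type"] = table["cluster"].map(labels.names)
    return table


def top_k_upregulated(
    table: pd.DataFrame,
    cluster,
    k: int = 50,
    max_q: float = 0.05,
    name: str | None = None,
    species: str | None = None,
) -> GeneSet:
    """First ``k`` upregulated significant genes of a cluster's sorted rows.

    Keeps genes with lfc > 0 and q < ``max_q`` in table order (ascending p,
    then descending lfc). Returns fewer genes, with a warning, when fewer
    pass.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if cluster not in set(table["cluster"]):
        raise ValueError(f"unknown cluster {cluster!r}")
    rows = table[
        (table["cluster"] == cluster) & (table["lfc"] > 0) & (table["qval"] < max_q)
    ]
    genes = rows["gene"].tolist()[:k]
    if len(genes) < k:
        warnings.warn(
            f"cluster {cluster}: only {len(genes)} of {k} requested genes pass "
            "the significance filter",
            stacklevel=2,
        )
    if name is None:
        name = f"cluster{cluster}_top{k}"
    return GeneSet(name=name, genes=genes, species=species)


def derive_short_signature(
    table: pd.DataFrame,
    cluster,
    k: int = 20,
    cluster_names: Mapping | None = None,
    species: str | None = None,
) -> GeneSet:
    """Compact detection signature: top-k upregulated genes of one cluster.

    The signature is named after the cluster's cell type when a name is
    available (from ``cluster_names`` or the table's ``cell_type`` column).
    """
    name = None
    if cluster_names is not None and cluster in cluster_names:
        name = str(cluster_names[cluster])
    elif "cell_type" in table.columns:
        types = table.loc[table["cluster"] == cluster, "cell_type"].dropna().unique()
        if len(types):
            name = str(types[0])
    return top_k_upregulated(
        table, cluster, k=k, name=name, species=species
    )
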