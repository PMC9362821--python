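"""Cross-species cluster correspondence over one-to-one orthologues.

The procedure takes per-cluster top-k upregulated gene lists from each
species, keeps the genes with a one-to-one orthologue, builds the
deduplicated union panel, averages log-normalized expression per cluster
over the panel, z-scores each gene within each species across that species'
clusters, stacks the rows of both species on the shared panel and clusters
rows (cell populations) and columns (genes) agglomeratively — by default
Pearson correlation distance (1 - r) with average linkage (UPGMA). Cognate
populations are then assessed by whether they are mutual nearest
cross-species neighbours and whether their dendrogram join precedes any
join with a non-cognate row. A species-A signature can also be translated
through the one-to-one table and scored on species B directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .matrix import LogNormMatrix
from .ortho import OrthologueTable, one_to_one_filter
from .preprocess import ClusterLabels
from .signatures import GeneSet, ScoreVector, score_signature

__all__ = [
    "one_to_one_filter",
    "build_union_geneset",
    "cluster_profile_matrix",
    "Dendrogram",
    "hierarchical_correspondence",
    "correspondence_score",
    "project_signature",
]


def build_union_geneset(
    marker_sets_a: Sequence[GeneSet],
    marker_sets_b: Sequence[GeneSet],
    table: OrthologueTable,
) -> pd.DataFrame:
    """Deduplicated union of both species' top-k genes, as orthologue pairs.

    Genes without a one-to-one partner are dropped. Returns a DataFrame with
    columns ``gene_a``, ``gene_b`` and ``provenance`` (which contributing
    sets supplied the pair), ordered by first contribution. Raises if the
    resulting panel is empty.
    """
    a_to_b = table.a_to_b()
    b_to_a = table.b_to_a()
    panel: dict[tuple[str, str], list[str]] = {}
    for gs in marker_sets_a:
        for g in gs.genes:
            if g in a_to_b:
                panel.setdefault((g, a_to_b[g]), []).append(gs.name)
    for gs in marker_sets_b:
        for g in gs.genes:
            if g in b_to_a:
                panel.setdefault((b_to_a[g], g), []).append(gs.name)
    if not panel:
        raise ValueError("no marker gene has a one-to-one orthologue: empty panel")
    return pd.DataFrame(
        {
            "gene_a": [p[0] for p in panel],
            "gene_b": [p[1] for p in panel],
            "provenance": [";".join(v) for v in panel.values()],
        }
    )


def _cluster_means(
    lognorm: LogNormMatrix, labels: ClusterLabels, genes: Sequence[str]
) -> pd.DataFrame:
    missing = [g for g in genes if g not in lognorm.genes]
    if missing:
        raise ValueError(f"panel genes absent from matrix: {missing[:10]}")
    values = lognorm.values.loc[list(genes)]
    clusters = np.sort(labels.labels.unique())
    out = {}
    for c in clusters:
        cells = labels.labels[labels.labels == c].index
        if len(cells) == 0:
            raise ValueError(f"cluster {c} has no cells")
        out[c] = values.loc[:, cells].mean(axis=1)
    return pd.DataFrame(out)  # genes x clusters


def _zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row across columns (sample sd); zero variance -> zeros."""
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1) if df.shape[1] > 1 else pd.Series(0.0, index=df.index)
    sd = sd.fillna(0.0)
    z = df.sub(mu, axis=0).div(sd.where(sd > 0, 1.0), axis=0)
    z[sd <= 0] = 0.0
    return z


def cluster_profile_matrix(
    lognorm_a: LogNormMatrix,
    labels_a: ClusterLabels,
    lognorm_b: LogNormMatrix,
    labels_b: ClusterLabels,
    panel: pd.DataFrame,
    species: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Stacked (species, cluster) x panel matrix of z-scored cluster means.

    For each species, panel genes are averaged per cluster over that
    cluster's cells, then each gene is z-scored across that species'
    clusters (removing species-level scale before the rows are stacked).
    Columns are labelled ``gene_a|gene_b``; rows use the cluster's cell-type
    name when the labels carry one, else the cluster id.
    """
    cols = panel["gene_a"] + "|" + panel["gene_b"]
    rows = []
    for (lognorm, labels, genes, name) in [
        (lognorm_a, labels_a, panel["gene_a"], species[0]),
        (lognorm_b, labels_b, panel["gene_b"], species[1]),
    ]:
        means = _cluster_means(lognorm, labels, genes.tolist())
        z = _zscore_rows(means)
        block = z.T  # clusters x genes
        block.columns = cols
        names = labels.names or {}
        block.index = pd.MultiIndex.from_tuples(
            [(name, str(names.get(c, c))) for c in block.index],
            names=["species", "cluster"],
        )
        rows.append(block)
    return pd.concat(rows)


@dataclass
class Dendrogram:
    """Agglomeration result: SciPy linkage plus leaf labels.

    ``merges`` lists ``(node_i, node_j, height)`` with leaves numbered
    0..n-1 and internal nodes n, n+1, ... in merge order; heights are
    non-decreasing under average linkage.
    """

    linkage: np.ndarray
    labels: list[str]
    metric: str
    method: str

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        return [
            (int(a), int(b), float(h)) for a, b, h, _ in self.linkage
        ]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cophenetic(self) -> pd.DataFrame:
        """Pairwise merge heights between leaves."""
        dense = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(dense, index=self.labels, columns=self.labels)

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                label = str(self.labels[node.id]).replace(" ", "_")
                return f"{label}:{length:.6g}"
            inner = ",".join(fmt(ch, node.dist) for ch in (node.left, node.right))
            return f"({inner}):{length:.6g}"

        inner = ",".join(fmt(ch, tree.dist) for ch in (tree.left, tree.right))
        return f"({inner});"

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "merges": self.merges,
            "metric": self.metric,
            "method": self.method,
        }


def _row_labels(index: pd.Index) -> list[str]:
    if isinstance(index, pd.MultiIndex):
        return [":".join(map(str, tup)) for tup in index]
    return [str(x) for x in index]


def hierarchical_correspondence(
    profile: pd.DataFrame,
    metric: str = "correlation",
    method: str = "average",
    axis: str = "rows",
) -> Dendrogram:
    """Agglomerative clustering of profile rows (or columns).

    Default is Pearson correlation distance with average linkage (UPGMA).
    Raises on NaN values or on constant rows (undefined correlation).
    """
    data = profile if axis == "rows" else profile.T
    if data.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    X = data.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("profile contains NaN")
    if metric == "correlation" and (X.std(axis=1) == 0).any():
        raise ValueError("constant rows have undefined correlation distance")
    dist = pdist(X, metric=metric)
    if np.isnan(dist).any():
        raise ValueError("distance computation produced NaN")
    Z = hierarchy.linkage(dist, method=method)
    labels = _row_labels(data.index)
    return Dendrogram(linkage=Z, labels=labels, metric=metric, method=method)


def correspondence_score(
    profile: pd.DataFrame,
    cognate_pairs: Sequence[tuple],
    metric: str = "correlation",
    method: str = "average",
) -> pd.DataFrame:
    """Per-cognate-pair correspondence report.

    For each pair of rows (one per species): the profile distance, whether
    each row is the other's nearest row from the other species
    (``mutual_nearest``), and whether their dendrogram join precedes any
    join of either with a row outside the pair (``joined_first``).
    """
    labels = _row_labels(profile.index)
    pos = {lab: i for i, lab in enumerate(labels)}
    species = [
        tup[0] if isinstance(profile.index, pd.MultiIndex) else lab.split(":")[0]
        for tup, lab in zip(profile.index, labels)
    ]

    def resolve(item) -> int:
        lab = ":".join(map(str, item)) if isinstance(item, tuple) else str(item)
        if lab not in pos:
            raise ValueError(f"unknown profile row {lab!r}")
        return pos[lab]

    D = squareform(pdist(profile.to_numpy(dtype=float), metric=metric))
    dendro = hierarchical_correspondence(profile, metric=metric, method=method)
    C = squareform(hierarchy.cophenet(dendro.linkage))
    n = len(labels)

    records = []
    for pair in cognate_pairs:
        ia, ib = resolve(pair[0]), resolve(pair[1])
        rec = {"pair": f"{labels[ia]}~{labels[ib]}", "distance": float(D[ia, ib])}
        mutual = True
        for i, j in [(ia, ib), (ib, ia)]:
            others = [x for x in range(n) if species[x] != species[i]]
            nearest = min(others, key=lambda x: (D[i, x], x))
            mutual &= nearest == j
        rec["mutual_nearest"] = mutual
        outside = [x for x in range(n) if x not in (ia, ib)]
        if outside:
            min_out = min(min(C[ia, x], C[ib, x]) for x in outside)
            rec["joined_first"] = bool(C[ia, ib] < min_out)
        else:
            rec["joined_first"] = True
        records.append(rec)
    return pd.DataFrame(records).set_index("pair")


def project_signature(
    sig: GeneSet,
    table: OrthologueTable,
    lognorm_b: LogNormMatrix,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> tuple[ScoreVector, dict]:
    """Translate a signature through the one-to-one table and score it.

    Mapping direction is inferred: signature genes are looked up in the
    table's A column first, then in the B column. Returns the score vector
    on the target matrix plus a report of mapped and dropped genes.
    """
    a_to_b = table.a_to_b()
    mapped = {g: a_to_b[g] for g in sig.genes if g in a_to_b}
    if not mapped:
        b_to_a = table.b_to_a()
        mapped = {g: b_to_a[g] for g in sig.genes if g in b_to_a}
    dropped = [g for g in sig.genes if g not in mapped]
    if not mapped:
        raise ValueError(
            f"no gene of signature {sig.name!r} has a one-to-one orthologue; "
            f"genes: {sig.genes}"
        )
    translated = GeneSet(
        name=f"{sig.name}_projected",
        genes=list(mapped.values()),
        species=None,
        source=sig.source,
    )
    score = score_signature(
        lognorm_b, translated, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed
    )
    return score, {"mapped": mapped, "dropped": dropped}
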